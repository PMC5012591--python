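# tumblekit run configuration (flat key = value; '#' starts a comment)
#
# Without yp/tb the pipeline runs in population mode: protein numbers are
# sampled per cell, the pathway model supplies each cell's CheY-P, and the
# estimated tumble biases are mapped back over (log CheR, log CheB).

seed = 1
n_cells = 200
duration = 120          # s per trajectory
out_dir = runs/demo
min_duration = 10       # s, shorter trajectories are discarded
tol = 0.01              # classifier outer-loop state-change tolerance
bandwidth = 0.2         # local-regression nearest-neighbor fraction
with_lna = true         # receptor-adaptation signaling noise

# uncomment for a fixed-phenotype run instead:
# tb = 0.25             # target tumble bias (or: yp = 2.75, in uM)

# any parameter of the four groups can be overridden:
# motor.epsilon = 1.3   # 1/s
# motor.g = 40          # switching gain
# motor.K_D = 3.06      # uM
swim.loc_noise = 0.1    # um, tracking localization error
# swim.speed = 20       # um/s
# swim.D_rot = 0.062    # rad^2/s
# swim.depth = 10       # um
# pathway.k_R = 0.04    # 1/s
# pathway.k_Q = 0.64    # 1/s
# noise.eta_int = 0.125
# noise.eta_ext = 0.26
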