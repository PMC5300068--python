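"""Monte-Carlo linker search against a synthetic bent target.

The full recovery experiment: a ground-truth conformation bent to 120
degrees is drawn, its noisy nine-curve SAXS series is simulated and pooled,
and a 600-trial dihedral search from the straight start is ranked by the
R factor.  The best-fit ensemble's bend angle and sedimentation
coefficients are compared with the truth.
"""

from flexscat.sampling import SearchConfig
from flexscat.synthetic import NoiseModel, ToyDimerSpec, recovery_experiment

rep = recovery_experiment(ToyDimerSpec(bend_angle_deg=120.0), NoiseModel(),
                          n_trials=600, seed=1, config=SearchConfig())

print(f"ground truth bend angle: {rep.true_theta:.1f} deg "
      f"(separation {rep.true_separation:.2f} nm)")
print(f"recovered (10 best of {rep.n_accepted} accepted / "
      f"{rep.n_proposed} proposed): {rep.recovered_theta_mean:.1f} "
      f"+- {rep.recovered_theta_sd:.1f} deg")
print(f"R factor: straight start {rep.start_r_factor:.1f}% -> "
      f"best fit {rep.best_r_factor:.1f}%")
print(f"s20,w: start {rep.s20w_start:.2f} S, truth {rep.s20w_truth:.2f} S, "
      f"best-fit mean {rep.s20w_best_mean:.2f} S")
# the bent models are more compact, so they fit the curve far better than
# the straight start AND sediment faster - the two independent signatures
# of a bent solution structure
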