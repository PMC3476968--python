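"""Normalized EMG amplitude by state, with a rank-sum test.

Wake epochs carry visibly higher anterior-tibialis EMG amplitude than
sleep epochs; this script quantifies the contrast on a synthetic night:
amplitudes are normalized by the recording's maximum, histograms are
accumulated per state, and a two-sample Wilcoxon rank-sum test compares
the per-epoch mean normalized amplitude between states.
"""

from emgsleep import SyntheticSpec, simulate_night, state_amplitude_histogram

spec = SyntheticSpec(duration_epochs=100, target_se=80.0, seed=5)
recording, truth, _ = simulate_night(spec)

result = state_amplitude_histogram(recording, truth, bins=30)
for state, means in result.epoch_means.items():
    print(f"{state:<6} {len(means):>3} epochs, mean normalized amplitude {means.mean():.4f}")
print(f"rank-sum test p-value: {result.p_value:.2e}")
print("significant at 0.05" if result.p_value < 0.05 else "not significant")

# a small p-value confirms the amplitude contrast the estimators
# exploit; on real data this is the sanity check to run first.
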