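"""Permutation validation: valid vs stimulus-shuffled TRF amplitudes.

On the seed-0 synthetic study, envelopes are deranged relative to the
EEG and the identical pipeline re-run; peak GFP amplitudes in the three
planted component windows are compared between valid and shuffled TRFs
by paired t-tests with FDR. Genuine stimulus-response coupling shows as
valid >> shuffled in every window; cross-validated prediction metrics
(MSE, Pearson r) of both arms are also reported.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from envtrf import simulate as sim
from envtrf.permutation import run_permutation
from envtrf.simulate import planted_windows

SEED = 0
LAMBDA = 1.0
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    cfg = sim.SimConfig(seed=SEED)
    study = sim.simulate_averaged_study(cfg)
    result = run_permutation(study.envelopes, study.responses, cfg.lag_spec, LAMBDA,
                             planted_windows(), seed=SEED + 1,
                             onset_index=cfg.onset_index, compute_metrics=True)
    print(result.stats.to_string(index=False))
    result.stats.to_csv(OUT / "permutation.csv", index=False, float_format="%.9g")

    vm = result.valid_metrics.groupby("condition")[["mse", "pearson_r"]].mean()
    sm = result.shuffled_metrics.groupby("condition")[["mse", "pearson_r"]].mean()
    print("\nvalid LOO metrics (mean over subjects):\n", vm)
    print("shuffled LOO metrics:\n", sm)
    result.valid_metrics.to_csv(OUT / "metrics_valid.csv", index=False, float_format="%.9g")
    result.shuffled_metrics.to_csv(OUT / "metrics_shuffled.csv", index=False,
                                   float_format="%.9g")
    print(f"wrote permutation.csv, metrics_valid.csv, metrics_shuffled.csv")


if __name__ == "__main__":
    main()
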