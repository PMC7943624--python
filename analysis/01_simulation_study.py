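"""Gaussian simulation study: does including noise features hurt clustering?

Simulates 40 replicates of 100 samples x 10,000 features where only the
first 100 features carry a one-SD group shift, then clusters
(Ward/Euclidean, cut to 2) on: the informative features only, all
features, and the top-k features by SD for k = 100, 200, ..., 10,000.

Findings with the committed seed: informative-only clustering recovers the
labels essentially perfectly (mean ARI ~ 1.0); including all 10,000
features dilutes the signal to mean ARI ~ 0.3; the SD-selected curve peaks
at a few hundred features — well above the all-features baseline — and
declines as more noise features enter.

Writes results/simulation_study/{summary.json,sd_sweep.tsv}.
"""

import json
from pathlib import Path

import pandas as pd

from featclust import GaussianSimConfig, run_simulation_study
from featclust.evaluate import running_mean

OUT = Path(__file__).resolve().parent.parent / "results" / "simulation_study"
SEED = 2021


def main() -> None:
    cfg = GaussianSimConfig(seed=SEED)
    print(f"running {cfg.n_replicates} replicates of "
          f"{cfg.n_features} features x {2 * cfg.n_per_group} samples ...")
    study = run_simulation_study(cfg)

    mean_curve = study.mean_sweep()
    smoothed = pd.Series(
        running_mean(mean_curve.to_numpy(), 5), index=mean_curve.index
    )
    k_star = int(smoothed.idxmax())

    OUT.mkdir(parents=True, exist_ok=True)
    summary = {
        "seed": SEED,
        "n_replicates": cfg.n_replicates,
        "mean_ari_informative_only": study.mean_ari_informative,
        "mean_ari_all_features": study.mean_ari_all,
        "sd_sweep_peak_k": k_star,
        "sd_sweep_peak_ari": float(smoothed.max()),
    }
    with open(OUT / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    pd.DataFrame(
        {"mean_ari": mean_curve, "smoothed": smoothed}
    ).to_csv(OUT / "sd_sweep.tsv", sep="\t", index_label="k")

    print(f"informative only : mean ARI = {study.mean_ari_informative:.4f}")
    print(f"all features     : mean ARI = {study.mean_ari_all:.4f}")
    print(f"SD sweep         : peak at k = {k_star} "
          f"(smoothed mean ARI {smoothed.max():.3f})")
    print(f"results in {OUT}")


if __name__ == "__main__":
    main()
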