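"""Known-truth validation battery for the whole pipeline.

Runs the simulation experiments that score the analysis against the
generator's ground truth: ordering recovery, greedy-vs-exhaustive oracle
agreement, mixture parameter recovery, staging fidelity, longitudinal
directionality, and type-I calibration. Writes the summary to
results/validation_experiments.json.
"""

import json
from pathlib import Path

from ftdprog import experiments as ex

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 17


def main() -> None:
    OUT.mkdir(exist_ok=True)
    summary = {}

    summary["ordering_recovery"] = ex.ordering_recovery(
        n_seeds=20, separation_sd=2.0, seed=SEED)
    r = summary["ordering_recovery"]
    print(f"ordering recovery at 2-sd separation: {r['recovery_rate']:.0%} "
          f"of 20 seeds exact; mean Kendall tau distance "
          f"{r['mean_tau_distance']:.1f} of 36 pairs")
    print("  (late-event positions are weakly identified at this cohort "
          "composition: few symptomatic subjects lie between consecutive "
          "stage thresholds)")

    summary["greedy_oracle"] = ex.greedy_vs_exhaustive(seed=SEED)
    print(f"greedy vs exhaustive ordering cost agreement: "
          f"{summary['greedy_oracle']['agreement_rate']:.0%} of 100 instances")

    summary["gmm_recovery"] = ex.gmm_recovery(seed=SEED)
    print(f"mixture recovery (N(0,1) vs N(5,1), n=1000): worst mean error "
          f"{summary['gmm_recovery']['max_mean_error']:.3f}")

    summary["staging"] = ex.staging_quality(seed=SEED)
    s = summary["staging"]
    print(f"staging: CV AUC {s['auc_mean']:.2f} +/- {s['auc_sd']:.2f}; "
          f"stage vs latent-stage Spearman {s['stage_latent_spearman']:.2f} "
          f"over {s['n_carriers']} carriers "
          f"({s['stage_latent_spearman_all']:.2f} incl. the control tie block)")

    summary["directionality"] = ex.directionality_recovery(n_seeds=50,
                                                           seed=SEED)
    d = summary["directionality"]
    print(f"directionality: all 3 coupled WMH->subcortical pairs detected in "
          f"{d['forward_all_significant_rate']:.0%} of 50 seeds; reverse "
          f"false-positive rate {d['reverse_false_positive_rate']:.3f}")

    summary["type_one"] = ex.type_one_calibration(n_sims=1000, seed=SEED)
    t = summary["type_one"]
    print(f"type-I calibration at alpha 0.05 (1000 sims): screen "
          f"{t['screen_rate']:.3f}, group {t['group_rate']:.3f}, "
          f"pair {t['pair_rate']:.3f}")

    (OUT / "validation_experiments.json").write_text(
        json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
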