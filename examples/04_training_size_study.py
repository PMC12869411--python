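"""How many training images does the observer need?

Repeats training on fresh data of growing size M (pairs per class) against one
fixed test set, and tracks the across-trial standard error of the LROC AUC for
the unthresholded and thresholded prewhitening observers.  Prints the SE
curves and the plateau training size under the 20% rule (smallest size whose
SE is within 20% of the largest-size SE).  Several minutes on one CPU at this
reduced scale; raise n_trials/m_values for smoother curves.

Run: python examples/04_training_size_study.py [out.csv]
"""

import sys

from vsmo import (
    TrainingSizeConfig,
    plateau_training_size,
    run_training_size_study,
    summarize_training_study,
    write_results,
)


def main() -> None:
    config = TrainingSizeConfig(
        m_values=(30, 100, 300, 500),
        n_trials=5,
        n_test_pairs=200,
        seed=11,
    )
    table = run_training_size_study(config, verbose=True)
    summary = summarize_training_study(table)
    print(f"\n{'variant':>14} {'M pairs':>8} {'total':>6} {'mean AUC':>9} {'SE':>8}")
    for _, row in summary.iterrows():
        print(
            f"{row['variant']:>14} {row['m_pairs']:8d} {row['total_train_cases']:6d} "
            f"{row['auc_lroc_mean']:9.3f} {row['se']:8.4f}"
        )
    for variant in ("pw", "pw_threshold"):
        total = plateau_training_size(summary, variant)
        print(f"plateau (20% rule) for {variant}: {total} total training cases")
    if len(sys.argv) > 1:
        write_results(table, sys.argv[1], config=config, plots=True)
        print(f"wrote {sys.argv[1]} (+ manifest and plot)")


if __name__ == "__main__":
    main()
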