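"""Aperture trade-off: sweep the relative pinhole diameter.

Small pinholes starve the image of counts (quantum noise); large ones blur the
lesion away.  This sweeps a coarse grid of relative diameters with the
prewhitening visual-search observer and prints the LROC AUC per setting; the
curve peaks near a relative diameter of 1.0 (pinhole FWHM equal to the lesion
FWHM).  A few minutes on one CPU at this reduced scale.

Run: python examples/03_pinhole_sweep.py [out.csv]
"""

import sys

from vsmo import SweepConfig, run_pinhole_sweep, write_results


def main() -> None:
    config = SweepConfig(
        d_rel_values=(0.4, 1.0, 2.0, 3.0),
        observer_variants=("pw",),
        n_train_pairs=100,
        n_test_pairs=100,
        seed=11,
    )
    table = run_pinhole_sweep(config, verbose=True)
    print(f"\n{'d_rel':>6} {'LROC AUC':>9} {'ROC AUC':>8} {'P(correct loc)':>15}")
    for _, row in table.iterrows():
        print(
            f"{row['d_rel']:6.1f} {row['auc_lroc']:9.3f} "
            f"{row['auc_roc']:8.3f} {row['pcl']:15.2f}"
        )
    best = table.loc[table["auc_lroc"].idxmax()]
    print(f"\nbest relative diameter: {best['d_rel']:.1f} (LROC AUC {best['auc_lroc']:.3f})")
    if len(sys.argv) > 1:
        write_results(table, sys.argv[1], config=config, plots=True)
        print(f"wrote {sys.argv[1]} (+ manifest and plot)")


if __name__ == "__main__":
    main()
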