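"""End-to-end walkthrough: simulate, train, rate, score.

Generates a paired lesion-present/absent dataset of pinhole images over lumpy
backgrounds, trains the two-stage visual-search observer (thresholded and
unthresholded variants share one stage-1 fit), rates a held-out test set and
reports ROC/LROC figures of merit.  Scaled down (60 training pairs, 60 test
pairs) so it finishes in about a minute on one CPU.

Run: python examples/01_simulate_fit_rate.py
"""

from vsmo import (
    ApertureModel,
    PhantomConfig,
    ObserverConfig,
    default_filter_bank,
    empirical_lroc_auc,
    empirical_roc_auc,
    generate_dataset,
)
from vsmo.experiments import calibrate_refined_bank
from vsmo.observer import extract_case_features, fit_observer_base, make_observer, score_cases


def main() -> None:
    phantom = PhantomConfig()  # 128 px, 50 lumps, 9.4 px FWHM lesion
    aperture = ApertureModel(relative_diameter=1.0)  # pinhole FWHM = lesion FWHM
    config = ObserverConfig()  # prewhitening, 3 search + 3 decision features

    print("simulating 60 training and 60 test pairs ...")
    train = generate_dataset(phantom, aperture, n_pairs=60, seed=1)
    test = generate_dataset(phantom, aperture, n_pairs=60, seed=2)

    print("refining the 48-kernel Gabor bank to 12 kernels ...")
    bank = default_filter_bank()
    refined = calibrate_refined_bank(bank, phantom, aperture, n_pairs=60, seed=3)

    print("training the two-stage observer ...")
    base = fit_observer_base(train, bank, config, refined_indices=refined)
    observers = {
        "unthresholded": make_observer(base, thresholded=False),
        "thresholded": make_observer(base, thresholded=True),
    }

    # stage 1 is shared, so run it once over the test set
    cases = extract_case_features(test, base)
    radius = config.localization_radius_px
    for name, obs in observers.items():
        records = score_cases(cases, obs)
        lroc = empirical_lroc_auc(records, radius)
        roc = empirical_roc_auc(records)
        print(
            f"{name:>14}: ROC AUC = {roc.auc:.3f}   LROC AUC = {lroc.auc:.3f}   "
            f"correct localization = {lroc.correct_localization_fraction:.2f}"
        )
    thr = observers["thresholded"]
    finite = [f"{t:.1f}" if t > float("-inf") else "-inf" for t in thr.thresholds.thresholds]
    print(f"fitted decision thresholds: [{', '.join(finite)}]")
    print(f"branches in use: {sorted(thr.branches)}")


if __name__ == "__main__":
    main()
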