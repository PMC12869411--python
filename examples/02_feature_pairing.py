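"""Which feature should join the bank: a strong twin or a weaker complement?

For a fixed first feature with detectability SNR = 2, this prints the combined
Hotelling SNR of pairing it with (a) an equally strong feature and (b) a
half-strength feature, as their correlation grows.  At low correlation the
equal pair wins; past a crossover the redundant strong twin loses to the less
correlated weak partner — the rule the 48-to-12 bank refinement exploits.

Run: python examples/02_feature_pairing.py  (instant)
"""

import numpy as np

from vsmo import auc_from_snr, pair_performance_curve


def main() -> None:
    s = 2.0
    rhos = np.arange(0.0, 1.0, 0.1)
    equal = pair_performance_curve(s, s, rhos)
    weak = pair_performance_curve(s, s / 2.0, rhos)
    print(f"first feature SNR = {s}; partner SNR = {s} (equal) or {s / 2} (weak)")
    print(f"{'rho':>5} {'SNR equal':>10} {'SNR weak':>10} {'AUC equal':>10} {'AUC weak':>10}")
    for rho, se, sw in zip(rhos, equal, weak):
        mark = "  <- weak partner now better" if sw > se else ""
        print(
            f"{rho:5.1f} {se:10.3f} {sw:10.3f} "
            f"{auc_from_snr(se):10.4f} {auc_from_snr(sw):10.4f}{mark}"
        )
    # analytic crossover for the equal pair vs s, s/2 pairing
    print("\nthe equal pair's combined SNR falls with correlation (2 s^2 / (1 + rho));")
    print("the weak partner's contribution survives because it is less redundant.")


if __name__ == "__main__":
    main()
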