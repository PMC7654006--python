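"""Independent brute-force oracles shared by the unit and acceptance tests.

These deliberately avoid the package's own code paths: correlation goes through
scipy, and the Hardy-Weinberg null is enumerated directly from log-factorial
probabilities instead of the implementation's recurrence.
"""
import numpy as np
from scipy.special import gammaln


def hwe_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided HWE p-value by full enumeration of heterozygote counts."""
    n = n_AA + n_Aa + n_aa
    rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if rare == 0:
        return 1.0

    def log_prob(het):
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        return (
            het * np.log(2.0)
            + gammaln(n + 1) - gammaln(het + 1) - gammaln(hom_r + 1) - gammaln(hom_c + 1)
            + gammaln(rare + 1) + gammaln(2 * n - rare + 1) - gammaln(2 * n + 1)
        )

    hets = np.arange(rare % 2, rare + 1, 2)
    probs = np.exp(np.array([log_prob(h) for h in hets]))
    probs /= probs.sum()
    p_obs = probs[list(hets).index(n_Aa)]
    return min(1.0, float(probs[probs <= p_obs * (1 + 1e-10)].sum()))
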