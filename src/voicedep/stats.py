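"""Binomial significance of an accuracy lift over chance.

Under the null hypothesis the classifier matches a baseline with accuracy
p0 on each of n_test independent patients, so the per-fold mean accuracy has
standard deviation sigma = sqrt(p0 (1 - p0) / n_test); averaging k
cross-validation folds scales it to sigma' = sigma / sqrt(k). The observed
lift is standardised to Z = lift / sigma' and assessed one-tailed against
the standard normal, p = 1 - Phi(Z). No continuity correction is applied.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

from scipy.stats import norm


@dataclass(frozen=True)
class SignificanceReport:
    n_test: int
    k: int
    p0: float
    lift: float
    sigma: float
    sigma_prime: float
    z: float
    p_one_tailed: float

    def to_dict(self) -> dict:
        return asdict(self)


def chance_sigma(n_test: int, p0: float) -> float:
    """Standard deviation of the mean accuracy of n_test Bernoulli(p0) trials."""
    if n_test < 1:
        raise ValueError("n_test must be at least 1")
    if not 0.0 < p0 < 1.0:
        raise ValueError("degenerate null: p0 must lie strictly in (0, 1)")
    return (p0 * (1.0 - p0) / n_test) ** 0.5


def fold_averaged_sigma(sigma: float, k: int) -> float:
    """Sd of the k-fold average of fold accuracies: sigma / sqrt(k)."""
    if k < 1:
        raise ValueError("k must be at least 1")
    return sigma / k**0.5


def lift_significance(lift: float, sigma_prime: float) -> tuple[float, float]:
    """Standardised lift and its one-tailed normal p-value."""
    if sigma_prime <= 0:
        raise ValueError("sigma_prime must be positive")
    z = lift / sigma_prime
    return float(z), float(norm.sf(z))


def significance_report(
    n_test: int, k: int, p0: float, lift: float
) -> SignificanceReport:
    """Full chain: sigma -> sigma' -> Z -> one-tailed p."""
    sigma = chance_sigma(n_test, p0)
    sigma_prime = fold_averaged_sigma(sigma, k)
    z, p = lift_significance(lift, sigma_prime)
    return SignificanceReport(
        n_test=n_test, k=k, p0=p0, lift=lift,
        sigma=sigma, sigma_prime=sigma_prime, z=z, p_one_tailed=p,
    )
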