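"""Metabolic scaling expectations and the CI-containment support test.

If metabolic rate scales with body mass as M^m, then life-history traits
inherit predictable exponents: b = m for rates of biomass production,
b = 1 - m for biological times, b = m - 1 for biological rates, and
b = m + (1 - m) = 1 for biomass products (a production rate accumulated over
a biological time; exponents of composed quantities add).  The metabolic
driver hypothesis (MDH) uses a taxon-specific m (0.88 for amphibians); the
metabolic theory of ecology (MTE) fixes m = 3/4 (Kleiber's law).

A fitted allometry *supports* an expected exponent when its slope differs
significantly from zero and the expected value lies inside the slope's 95%
confidence interval (inclusive endpoints).
"""

from __future__ import annotations

from dataclasses import dataclass

from .pgls import PGLSFit, significant_positive

__all__ = [
    "CATEGORIES",
    "DEFAULT_TRAIT_CATEGORIES",
    "DEFAULT_METABOLIC_EXPONENTS",
    "ScalingExpectation",
    "SupportDecision",
    "expected_exponent",
    "assess_support",
    "count_support",
    "count_significant_positive",
    "compare_fits",
]

CATEGORIES = ("biomass_product", "production_rate", "biological_time", "biological_rate")

#: Default trait -> category assignment for the eight testable traits.
DEFAULT_TRAIT_CATEGORIES: dict[str, str] = {
    "clutch_volume": "biomass_product",
    "juvenile_mass": "biomass_product",
    "annual_clutch_volume": "production_rate",
    "annual_clutch_number": "biological_rate",
    "incubation_time": "biological_time",
    "larval_period": "biological_time",
    "age_at_maturity": "biological_time",
    "max_longevity": "biological_time",
}

DEFAULT_METABOLIC_EXPONENTS: dict[str, float] = {"MDH": 0.88, "MTE": 0.75}


def expected_exponent(category: str, m: float) -> float:
    """Expected allometric exponent for a trait category under metabolic exponent m."""
    if not 0.0 < m < 1.0:
        raise ValueError(f"metabolic exponent m must lie in (0, 1), got {m}")
    if category == "production_rate":
        return m
    if category == "biological_time":
        return 1.0 - m
    if category == "biological_rate":
        return m - 1.0
    if category == "biomass_product":
        return 1.0  # m + (1 - m): production rate times biological time
    raise ValueError(f"unknown trait category {category!r}")


@dataclass(frozen=True)
class ScalingExpectation:
    trait: str
    category: str
    m: float
    hypothesis: str  # "MDH" or "MTE"

    @property
    def expected_b(self) -> float:
        return expected_exponent(self.category, self.m)


@dataclass(frozen=True)
class SupportDecision:
    trait: str
    hypothesis: str
    expected_b: float
    slope_significant: bool
    expected_in_ci: bool

    @property
    def support(self) -> bool:
        return self.slope_significant and self.expected_in_ci


def assess_support(
    fit: PGLSFit,
    expectation: ScalingExpectation,
    alpha: float = 0.05,
    slope_significant: bool | None = None,
) -> SupportDecision:
    """Test whether a fitted slope supports the expected exponent.

    Significance defaults to the fit's two-sided slope p-value against
    ``alpha``; pass ``slope_significant`` explicitly when replaying printed
    tables, where significance is equivalently read off the CI excluding
    zero.  CI containment uses inclusive endpoints.
    """
    exp_b = expectation.expected_b
    if slope_significant is None:
        slope_significant = fit.p_slope < alpha
    lo, hi = fit.ci_slope
    in_ci = lo <= exp_b <= hi
    return SupportDecision(
        trait=expectation.trait,
        hypothesis=expectation.hypothesis,
        expected_b=exp_b,
        slope_significant=bool(slope_significant),
        expected_in_ci=bool(in_ci),
    )


def count_support(decisions: list[SupportDecision]) -> int:
    """Number of decisions with support == True (one hypothesis at a time)."""
    hyps = {d.hypothesis for d in decisions}
    if len(hyps) > 1:
        raise ValueError(f"decisions mix hypotheses: {sorted(hyps)}")
    return sum(d.support for d in decisions)


def count_significant_positive(fits: list[PGLSFit], alpha: float = 0.05) -> int:
    """Number of fits with a significant, positive slope."""
    return sum(significant_positive(f, alpha) for f in fits)


def compare_fits(fit1: PGLSFit, fit2: PGLSFit, alpha: float = 0.05) -> dict[str, str]:
    """Compare two allometries parameter-wise via 95% CI overlap.

    Applicable only to parameters that are significantly non-zero in both
    fits; a parameter is "different" iff the two intervals share no point
    (touching endpoints count as overlap).  Inapplicable parameters return
    ``"inapplicable: ..."`` with the reason.
    """
    out: dict[str, str] = {}
    for name, ci1, ci2, p1, p2 in (
        ("slope", fit1.ci_slope, fit2.ci_slope, fit1.p_slope, fit2.p_slope),
        ("intercept", fit1.ci_intercept, fit2.ci_intercept, fit1.p_intercept, fit2.p_intercept),
    ):
        if p1 >= alpha or p2 >= alpha:
            out[name] = "inapplicable: parameter not significantly non-zero in both fits"
            continue
        disjoint = ci1[1] < ci2[0] or ci2[1] < ci1[0]
        out[name] = "different" if disjoint else "not_different"
    return out
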