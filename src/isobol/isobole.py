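"""Fixed-ratio (type I) isobolographic analysis of drug mixtures.

Under Loewe additivity, a mixture whose components each contribute a fixed
fraction of their own ED50 ("equi-effective" fixed ratio; 1:1:1 means one
third of each component's ED50, not equal mg/kg) has predicted total ED50

    ED50_add = sum_i f_i * ED50_i,      SEM_add = sqrt(sum_i f_i^2 SEM_i^2)

where f_i are the fixed-ratio fractions.  The experimentally determined
mixture ED50 (ED50_exp) is compared with ED50_add by an unpaired two-tailed
Student t-test on the dose scale; the interaction index ED50_exp/ED50_add
together with significance classifies the interaction as supra-additive
(synergy, index < 1), sub-additive (antagonism, index > 1) or additive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .doseresponse import ParallelismResult, ProbitFit

__all__ = [
    "MixtureSpec",
    "MixtureED50",
    "InteractionResult",
    "RatioPolicy",
    "additive_mixture_ed50",
    "mixture_composition",
    "eligible_fixed_ratios",
    "compare_mixture_ed50",
    "isobologram_projections",
]

_FRACTION_TOL = 1e-12


@dataclass(frozen=True)
class MixtureSpec:
    """An ordered fixed-ratio mixture of k >= 2 drugs.

    ``fractions[i]`` is the fraction of drug i's own ED50 contributed to
    the mixture; the fractions must sum to 1.  ``from_ratio("1:1:1")``
    builds the equi-effective three-drug spec with fractions (1/3, 1/3, 1/3).
    """

    drug_ids: tuple[str, ...]
    fractions: tuple[float, ...]
    ratio_label: str = ""

    def __post_init__(self) -> None:
        if len(self.drug_ids) < 2:
            raise ValueError("a mixture needs at least 2 components")
        if len(self.drug_ids) != len(self.fractions):
            raise ValueError("drug_ids and fractions must have equal length")
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValueError("duplicate drug_ids in mixture")
        if any(f <= 0 for f in self.fractions):
            raise ValueError("all fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > _FRACTION_TOL:
            raise ValueError(
                f"fractions must sum to 1, got {sum(self.fractions)!r}"
            )
        object.__setattr__(self, "drug_ids", tuple(self.drug_ids))
        object.__setattr__(self, "fractions", tuple(float(f) for f in self.fractions))
        if not self.ratio_label:
            object.__setattr__(self, "ratio_label", self._derive_label())

    def _derive_label(self) -> str:
        fracs = [Fraction(f).limit_denominator(10**6) for f in self.fractions]
        denom = math.lcm(*(fr.denominator for fr in fracs))
        parts = [fr.numerator * denom // fr.denominator for fr in fracs]
        g = math.gcd(*parts)
        return ":".join(str(p // g) for p in parts)

    @classmethod
    def from_ratio(cls, drug_ids: Sequence[str], ratio: str) -> "MixtureSpec":
        """Build a spec from a ratio string such as ``"1:1:1"`` or ``"1:3"``."""
        parts = [float(p) for p in ratio.split(":")]
        if len(parts) != len(drug_ids):
            raise ValueError(
                f"ratio {ratio!r} has {len(parts)} parts for {len(drug_ids)} drugs"
            )
        total = sum(parts)
        return cls(tuple(drug_ids), tuple(p / total for p in parts), ratio_label=ratio)

    @property
    def is_equieffective(self) -> bool:
        return all(abs(f - self.fractions[0]) < _FRACTION_TOL for f in self.fractions)


@dataclass(frozen=True)
class MixtureED50:
    """A mixture's total-dose ED50 +/- SEM with per-component breakdown.

    ``kind`` distinguishes the theoretically additive prediction from the
    experimentally fitted value; ``df`` is an animals-based degrees-of-
    freedom bookkeeping entry used by the t-test's df policy.
    """

    kind: Literal["additive_theoretical", "experimental"]
    total_ed50: float  # mg/kg
    sem: float  # mg/kg
    component_doses: Mapping[str, float]  # mg/kg, sums to total_ed50
    df: int

    def __post_init__(self) -> None:
        if not self.total_ed50 > 0:
            raise ValueError("total_ed50 must be positive")
        if not self.sem >= 0:
            raise ValueError("sem must be non-negative")
        if any(d <= 0 for d in self.component_doses.values()):
            raise ValueError("all component doses must be positive")
        s = sum(self.component_doses.values())
        if abs(s - self.total_ed50) > 1e-9 * self.total_ed50:
            raise ValueError(
                f"component doses sum to {s}, not total_ed50={self.total_ed50}"
            )
        object.__setattr__(self, "component_doses", dict(self.component_doses))


@dataclass(frozen=True)
class InteractionResult:
    """Classification of an experimental-vs-additive ED50 comparison."""

    t_statistic: float
    df: int
    p_value: float
    alpha: float
    interaction_index: float  # ED50_exp / ED50_add
    classification: Literal["supra_additive", "additive", "sub_additive"]


@dataclass(frozen=True)
class RatioPolicy:
    """Which fixed ratios are isobolographically interpretable."""

    all_parallel: bool
    eligible: Literal["all_ratios", "equieffective_only"]
    reason: str

    def allows(self, spec: MixtureSpec) -> bool:
        return self.eligible == "all_ratios" or spec.is_equieffective


def _fits_by_spec(fits: Sequence[ProbitFit], spec: MixtureSpec) -> list[ProbitFit]:
    if len(fits) != len(spec.drug_ids):
        raise ValueError(
            f"{len(fits)} fits supplied for {len(spec.drug_ids)} mixture components"
        )
    by_id = {f.drug_id: f for f in fits}
    if set(by_id) != set(spec.drug_ids):
        raise ValueError(
            f"fit drug_ids {sorted(by_id)} do not match mixture {spec.drug_ids}"
        )
    ordered = [by_id[d] for d in spec.drug_ids]
    for f in ordered:
        if not f.converged:
            raise ValueError(f"fit for {f.drug_id} did not converge")
    return ordered


def additive_mixture_ed50(
    fits: Sequence[ProbitFit], spec: MixtureSpec, df: int = 0
) -> MixtureED50:
    """Theoretically additive mixture ED50 from single-drug fits.

    Each component contributes ``fraction * ED50`` mg/kg; the total is their
    sum and the SEM propagates in quadrature assuming independent errors:
    ``sqrt(sum f_i^2 SEM_i^2)``.

    ``df`` records the animals-based degrees of freedom of the single-drug
    determinations (sum of animals across the component fits when 0).
    """
    ordered = _fits_by_spec(fits, spec)
    comp = {
        d: f_i * fit.ed50
        for d, f_i, fit in zip(spec.drug_ids, spec.fractions, ordered)
    }
    total = sum(comp.values())
    sem = math.sqrt(
        sum(f_i**2 * fit.sem_ed50**2 for f_i, fit in zip(spec.fractions, ordered))
    )
    if df == 0:
        df = sum(f.n_total for f in ordered)
    return MixtureED50(
        kind="additive_theoretical",
        total_ed50=total,
        sem=sem,
        component_doses=comp,
        df=df,
    )


def mixture_composition(
    total_dose: float, fits: Sequence[ProbitFit], spec: MixtureSpec
) -> dict[str, float]:
    """Split a total mixture dose into per-component doses.

    Components keep the fixed-ratio proportions ``f_i * ED50_i / sum_j f_j
    ED50_j``, so the breakdown at the additive total is exactly the additive
    component doses, and the per-component doses always sum to
    ``total_dose``.
    """
    if not total_dose > 0:
        raise ValueError("total_dose must be positive")
    ordered = _fits_by_spec(fits, spec)
    weights = np.array(
        [f_i * fit.ed50 for f_i, fit in zip(spec.fractions, ordered)], dtype=float
    )
    doses = total_dose * weights / weights.sum()
    # enforce exact conservation against float round-off
    doses[-1] = total_dose - doses[:-1].sum()
    return dict(zip(spec.drug_ids, doses.tolist()))


def eligible_fixed_ratios(
    parallelism: Mapping[tuple[str, str], ParallelismResult],
    drug_ids: Sequence[str],
) -> RatioPolicy:
    """Gate fixed-ratio choices on pairwise parallelism of the probit lines.

    If every component pair has parallel dose-response lines, any fixed
    ratio is isobolographically interpretable; if any pair is non-parallel,
    only the equi-effective ratio (1:1, 1:1:1, ...) is eligible, since only
    there do the components exert the same quantal effect irrespective of
    slope.
    """
    pairs = list(combinations(sorted(drug_ids), 2))
    norm = {tuple(sorted(k)): v for k, v in parallelism.items()}
    missing = [p for p in pairs if p not in norm]
    if missing:
        raise ValueError(f"incomplete parallelism matrix: missing pairs {missing}")
    nonpar = [p for p in pairs if not norm[p].parallel]
    if nonpar:
        detail = ", ".join(f"{a}-{b}" for a, b in nonpar)
        return RatioPolicy(
            all_parallel=False,
            eligible="equieffective_only",
            reason=(
                f"non-parallel dose-response lines ({detail}); only the "
                "equi-effective fixed ratio (1:1...) is interpretable"
            ),
        )
    return RatioPolicy(
        all_parallel=True,
        eligible="all_ratios",
        reason="all component dose-response lines are parallel",
    )


def compare_mixture_ed50(
    experimental: MixtureED50,
    additive: MixtureED50,
    alpha: float = 0.05,
    df: int | None = None,
    df_policy: Literal["explicit", "animals"] = "explicit",
) -> InteractionResult:
    """Unpaired two-tailed Student t comparison of ED50_exp vs ED50_add.

    t = (ED50_exp - ED50_add) / sqrt(SEM_exp^2 + SEM_add^2), signed so that
    a positive t means the mixture needed more total dose than additivity
    predicts.  The degrees of freedom are never invented: pass ``df``
    explicitly, or choose ``df_policy="animals"`` to use (animals behind the
    experimental mixture) + (animals behind the single-drug fits) - 4.

    Classification: sub_additive (antagonism) if p < alpha and the
    interaction index ED50_exp/ED50_add exceeds 1; supra_additive (synergy)
    if p < alpha and the index is below 1; additive otherwise.
    """
    if experimental.kind != "experimental" or additive.kind != "additive_theoretical":
        raise ValueError("expected one experimental and one additive MixtureED50")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    se = math.sqrt(experimental.sem**2 + additive.sem**2)
    index = experimental.total_ed50 / additive.total_ed50
    if se == 0:
        if experimental.total_ed50 == additive.total_ed50:
            # degenerate: identical point estimates with no error; df moot
            try:
                ddf = _resolve_df(experimental, additive, df, df_policy)
            except ValueError:
                ddf = 1
            return InteractionResult(0.0, ddf, 1.0, alpha, 1.0, "additive")
        raise ValueError("SEMs are zero but the ED50s differ; t is undefined")
    if experimental.sem <= 0 or additive.sem <= 0:
        raise ValueError("both SEMs must be positive")
    ddf = _resolve_df(experimental, additive, df, df_policy)
    t = (experimental.total_ed50 - additive.total_ed50) / se
    p = float(2.0 * stats.t.sf(abs(t), ddf))
    if p < alpha:
        label = "sub_additive" if index > 1 else "supra_additive"
    else:
        label = "additive"
    return InteractionResult(
        t_statistic=float(t),
        df=ddf,
        p_value=p,
        alpha=alpha,
        interaction_index=float(index),
        classification=label,
    )


def _resolve_df(
    experimental: MixtureED50,
    additive: MixtureED50,
    df: int | None,
    df_policy: str,
) -> int:
    if df is not None:
        if df < 1:
            raise ValueError("df must be a positive integer")
        return int(df)
    if df_policy == "animals":
        ddf = experimental.df + additive.df - 4
        if ddf < 1:
            raise ValueError("animals-based df is not positive")
        return ddf
    raise ValueError(
        "df must be supplied explicitly unless df_policy='animals' is chosen"
    )


def isobologram_projections(
    experimental: MixtureED50, additive: MixtureED50
) -> dict[tuple[str, str], dict[str, dict[str, tuple[float, float]]]]:
    """Pairwise 2-D projections of the additive (A) and experimental (M)
    mixture points for isobologram panels.

    For every unordered component pair (x, y) the result maps
    ``{"A": {"point": (dose_x, dose_y), "sem": (sem_x, sem_y)}, "M": ...}``
    where each mixture's total SEM is apportioned to components by the same
    proportions as its doses.  M lies above A on every panel exactly when
    ED50_exp > ED50_add.
    """
    if set(experimental.component_doses) != set(additive.component_doses):
        raise ValueError("mixtures have mismatched component drugs")
    drugs = list(experimental.component_doses)

    def point(mix: MixtureED50, x: str, y: str):
        dx, dy = mix.component_doses[x], mix.component_doses[y]
        return {
            "point": (dx, dy),
            "sem": (mix.sem * dx / mix.total_ed50, mix.sem * dy / mix.total_ed50),
        }

    out: dict = {}
    for x, y in combinations(drugs, 2):
        out[(x, y)] = {"A": point(additive, x, y), "M": point(experimental, x, y)}
    return out
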