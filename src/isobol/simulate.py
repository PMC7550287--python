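"""Synthetic quantal dose-response data with a controllable interaction.

The generator emulates the statistical structure of a fixed-ratio
combination experiment in a quantal seizure assay: groups of ~8 animals per
dose level whose protection counts are binomial draws from a probit law in
log10(dose), for single drugs and for a mixture whose true total ED50 is
``lambda_index`` times the additive prediction (lambda 1 = additive truth,
> 1 sub-additive, < 1 supra-additive).  Everything is seeded; identical
seed and scenario give byte-identical data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .doseresponse import (
    DoseGroup,
    Ed50NotIdentifiableError,
    FitConfig,
    ProbitFit,
    fit_log_probit,
)
from .isobole import (
    MixtureED50,
    MixtureSpec,
    additive_mixture_ed50,
    compare_mixture_ed50,
)

__all__ = [
    "TrueDrugParams",
    "MixtureScenario",
    "RecoveryReport",
    "auto_dose_levels",
    "scenario_from_file",
    "simulate_single_drug",
    "simulate_mixture_experiment",
    "recover_parameters",
]

# span the predicted 10%-90% response band so the ED50 is bracketed with
# high probability
_Z_SPAN = stats.norm.ppf(0.9)


@dataclass(frozen=True)
class TrueDrugParams:
    """Ground-truth probit line of one drug (generative counterpart of a fit)."""

    drug_id: str
    ed50_true: float  # mg/kg
    slope_true: float  # probits per log10(mg/kg)

    def __post_init__(self) -> None:
        if not (self.ed50_true > 0 and self.slope_true > 0):
            raise ValueError("ed50_true and slope_true must be positive")


@dataclass(frozen=True)
class MixtureScenario:
    """A complete simulated fixed-ratio experiment.

    Defaults mirror the quantal seizure assay design this emulates: four
    dose levels of eight animals per single drug and three levels of eight
    for the mixture, geometric dose spacing spanning the predicted 10-90%
    response band.  ``slope_mix`` defaults to the fraction-weighted mean of
    the component slopes; the mixture's true total ED50 is
    ``lambda_index * sum_i f_i ed50_true_i``.
    """

    components: tuple[TrueDrugParams, ...]
    spec: MixtureSpec
    lambda_index: float = 1.0
    slope_mix: float | None = None
    n_per_group: int = 8
    n_levels_single: int = 4
    n_levels_mixture: int = 3
    dose_levels: tuple[float, ...] | None = None  # mixture total doses
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lambda_index > 0:
            raise ValueError("lambda_index must be positive")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        ids = tuple(c.drug_id for c in self.components)
        if ids != self.spec.drug_ids:
            raise ValueError(
                f"component order {ids} must match mixture spec {self.spec.drug_ids}"
            )

    @property
    def additive_total_true(self) -> float:
        return sum(
            f * c.ed50_true for f, c in zip(self.spec.fractions, self.components)
        )

    @property
    def mixture_ed50_true(self) -> float:
        return self.lambda_index * self.additive_total_true

    @property
    def mixture_slope_true(self) -> float:
        if self.slope_mix is not None:
            return self.slope_mix
        return sum(
            f * c.slope_true for f, c in zip(self.spec.fractions, self.components)
        )


def scenario_from_file(path) -> MixtureScenario:
    """Load a scenario from a flat key=value file.

    Recognised keys: ``drugs`` (comma-separated ids), ``ed50s`` and
    ``slopes`` (comma-separated, aligned with drugs), ``ratio`` (e.g.
    ``1:1:1``), ``lambda_index``, ``slope_mix``, ``n_per_group``,
    ``n_levels_single``, ``n_levels_mixture``, ``dose_levels``
    (comma-separated mixture totals), ``seed``.  Lines starting with ``#``
    are comments.
    """
    kv: dict[str, str] = {}
    for raw in open(path, encoding="utf-8"):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}: expected key=value, got {line!r}")
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()
    for req in ("drugs", "ed50s", "slopes"):
        if req not in kv:
            raise ValueError(f"{path}: missing required key {req!r}")
    drugs = tuple(d.strip() for d in kv["drugs"].split(","))
    ed50s = [float(x) for x in kv["ed50s"].split(",")]
    slopes = [float(x) for x in kv["slopes"].split(",")]
    if not (len(drugs) == len(ed50s) == len(slopes)):
        raise ValueError(f"{path}: drugs/ed50s/slopes lengths differ")
    components = tuple(
        TrueDrugParams(d, e, s) for d, e, s in zip(drugs, ed50s, slopes)
    )
    spec = MixtureSpec.from_ratio(drugs, kv.get("ratio", ":".join("1" for _ in drugs)))
    return MixtureScenario(
        components=components,
        spec=spec,
        lambda_index=float(kv.get("lambda_index", 1.0)),
        slope_mix=float(kv["slope_mix"]) if "slope_mix" in kv else None,
        n_per_group=int(kv.get("n_per_group", 8)),
        n_levels_single=int(kv.get("n_levels_single", 4)),
        n_levels_mixture=int(kv.get("n_levels_mixture", 3)),
        dose_levels=(
            tuple(float(x) for x in kv["dose_levels"].split(","))
            if "dose_levels" in kv else None
        ),
        seed=int(kv.get("seed", 0)),
    )


def auto_dose_levels(ed50: float, slope: float, n_levels: int) -> np.ndarray:
    """Geometric dose ladder spanning the predicted 10%-90% response band."""
    if n_levels < 2:
        raise ValueError("need at least 2 dose levels")
    half_span = _Z_SPAN / slope  # in log10 dose units
    return np.logspace(
        math.log10(ed50) - half_span, math.log10(ed50) + half_span, n_levels
    )


def simulate_single_drug(
    params: TrueDrugParams,
    doses: Sequence[float],
    n_per_group: int,
    seed: int,
) -> list[DoseGroup]:
    """Draw one quantal dose-response dataset for a single drug.

    Each group's protected count is Binomial(n_per_group, p(d)) with
    p(d) = Phi(slope_true * (log10 d - log10 ed50_true)).
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("all doses must be positive")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    p = stats.norm.cdf(
        params.slope_true * (np.log10(doses) - math.log10(params.ed50_true))
    )
    k = rng.binomial(n_per_group, p)
    return [
        DoseGroup(params.drug_id, float(d), n_per_group, int(ki))
        for d, ki in zip(doses, k)
    ]


def _mixture_drug_id(scenario: MixtureScenario) -> str:
    return "+".join(scenario.spec.drug_ids)


def simulate_mixture_experiment(
    scenario: MixtureScenario,
) -> tuple[list[DoseGroup], float]:
    """Draw mixture total-dose groups; returns (groups, true additive total).

    The administered total doses follow the scenario's explicit
    ``dose_levels`` or an automatic geometric ladder bracketing the TRUE
    mixture ED50; the composition of every administered total dose keeps
    the fixed-ratio proportions of the true component ED50s.  Protection is
    binomial around a probit law in log10(total dose) with slope
    ``mixture_slope_true`` centred at ``lambda_index *`` additive total.
    """
    ed50_mix = scenario.mixture_ed50_true
    slope = scenario.mixture_slope_true
    if scenario.dose_levels is not None:
        doses = np.asarray(scenario.dose_levels, dtype=float)
        if np.any(doses <= 0):
            raise ValueError("all dose levels must be positive")
    else:
        doses = auto_dose_levels(ed50_mix, slope, scenario.n_levels_mixture)
    params = TrueDrugParams(_mixture_drug_id(scenario), ed50_mix, slope)
    groups = simulate_single_drug(params, doses, scenario.n_per_group, scenario.seed)
    return groups, scenario.additive_total_true


def mixture_true_composition(scenario: MixtureScenario, total_dose: float) -> dict[str, float]:
    """Per-component doses of an administered total, from the TRUE ED50s."""
    weights = np.array(
        [f * c.ed50_true for f, c in zip(scenario.spec.fractions, scenario.components)]
    )
    doses = total_dose * weights / weights.sum()
    return dict(zip(scenario.spec.drug_ids, doses.tolist()))


@dataclass(frozen=True)
class RecoveryReport:
    """Monte Carlo summary of the full pipeline run on simulated data."""

    replicates: int
    n_failed: int  # replicates lost to fit non-convergence / identifiability
    ed50_single_bias: dict[str, float]  # mean (fit - truth) / truth
    ed50_single_sd: dict[str, float]  # empirical SD of fitted ED50, mg/kg
    ed50_single_median: dict[str, float]
    ed50_mixture_bias: float
    ed50_mixture_sd: float
    ci_coverage_log_ed50: dict[str, float]  # 95% Wald CI on log10 ED50
    classification_counts: dict[str, int]
    mean_t: float
    alpha: float
    seed: int

    @property
    def n_ok(self) -> int:
        return self.replicates - self.n_failed

    def classification_rate(self, label: str) -> float:
        return self.classification_counts.get(label, 0) / max(self.n_ok, 1)


def _one_replicate(
    scenario: MixtureScenario, seed: int, alpha: float, fit_config: FitConfig
) -> tuple[dict[str, ProbitFit], ProbitFit, object] | None:
    """Simulate singles + mixture, fit everything, compare.  None on failure."""
    fits: dict[str, ProbitFit] = {}
    for i, comp in enumerate(scenario.components):
        doses = auto_dose_levels(
            comp.ed50_true, comp.slope_true, scenario.n_levels_single
        )
        groups = simulate_single_drug(
            comp, doses, scenario.n_per_group, seed=seed * 1000 + i
        )
        try:
            fit = fit_log_probit(groups, fit_config)
        except (Ed50NotIdentifiableError, ValueError):
            return None
        if not fit.converged:
            return None
        fits[comp.drug_id] = fit

    mix_scenario = replace(scenario, seed=seed * 1000 + len(scenario.components))
    mix_groups, _ = simulate_mixture_experiment(mix_scenario)
    try:
        mix_fit = fit_log_probit(mix_groups, fit_config)
    except (Ed50NotIdentifiableError, ValueError):
        return None
    if not mix_fit.converged:
        return None

    additive = additive_mixture_ed50(
        [fits[d] for d in scenario.spec.drug_ids], scenario.spec
    )
    comp_doses = {
        d: mix_fit.ed50 * w / additive.total_ed50
        for d, w in additive.component_doses.items()
    }
    experimental = MixtureED50(
        kind="experimental",
        total_ed50=mix_fit.ed50,
        sem=mix_fit.sem_ed50,
        component_doses=comp_doses,
        df=mix_fit.n_total,
    )
    result = compare_mixture_ed50(
        experimental, additive, alpha=alpha, df_policy="animals"
    )
    return fits, mix_fit, result


def recover_parameters(
    scenario: MixtureScenario,
    replicates: int,
    seed: int,
    alpha: float = 0.05,
    fit_config: FitConfig | None = None,
) -> RecoveryReport:
    """Run the full pipeline on many simulated experiments.

    Per replicate: simulate and fit each single drug, form the additive
    mixture ED50, simulate and fit the mixture, compare and classify.  Fit
    failures (non-convergence, unbracketed ED50) are counted, never raised.
    Reports per-drug bias, spread, 95% CI coverage of log10 ED50, the
    classification frequencies and the mean t statistic.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    fit_config = fit_config or FitConfig()
    rng = np.random.default_rng(seed)
    # independent sub-seeds, kept within int32 range
    sub_seeds = rng.integers(0, 2**31 - 1, size=replicates)

    ids = list(scenario.spec.drug_ids)
    ed50s: dict[str, list[float]] = {d: [] for d in ids}
    covered: dict[str, list[bool]] = {d: [] for d in ids}
    mix_ed50s: list[float] = []
    counts: dict[str, int] = {}
    ts: list[float] = []
    n_failed = 0

    z95 = stats.norm.ppf(0.975)
    true_by_id = {c.drug_id: c for c in scenario.components}

    for s in sub_seeds:
        out = _one_replicate(scenario, int(s), alpha, fit_config)
        if out is None:
            n_failed += 1
            continue
        fits, mix_fit, result = out
        for d in ids:
            fit = fits[d]
            ed50s[d].append(fit.ed50)
            lo = fit.log_ed50 - z95 * fit.sem_log_ed50
            hi = fit.log_ed50 + z95 * fit.sem_log_ed50
            covered[d].append(lo <= math.log10(true_by_id[d].ed50_true) <= hi)
        mix_ed50s.append(mix_fit.ed50)
        counts[result.classification] = counts.get(result.classification, 0) + 1
        ts.append(result.t_statistic)

    def _bias(vals: list[float], truth: float) -> float:
        return float(np.mean(vals) / truth - 1.0) if vals else math.nan

    return RecoveryReport(
        replicates=replicates,
        n_failed=n_failed,
        ed50_single_bias={
            d: _bias(ed50s[d], true_by_id[d].ed50_true) for d in ids
        },
        ed50_single_sd={
            d: float(np.std(ed50s[d], ddof=1)) if len(ed50s[d]) > 1 else math.nan
            for d in ids
        },
        ed50_single_median={
            d: float(np.median(ed50s[d])) if ed50s[d] else math.nan for d in ids
        },
        ed50_mixture_bias=_bias(mix_ed50s, scenario.mixture_ed50_true),
        ed50_mixture_sd=(
            float(np.std(mix_ed50s, ddof=1)) if len(mix_ed50s) > 1 else math.nan
        ),
        ci_coverage_log_ed50={
            d: float(np.mean(covered[d])) if covered[d] else math.nan for d in ids
        },
        classification_counts=counts,
        mean_t=float(np.mean(ts)) if ts else math.nan,
        alpha=alpha,
        seed=seed,
    )
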