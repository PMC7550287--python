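"""Reading/writing dose-group tables and the end-to-end analysis runner.

Dose groups travel as delimiter-separated text with a mandatory header:
``drug_id,dose_mg_per_kg,n_tested,n_protected[,pretreatment_min]``.
The runner chains the full fixed-ratio analysis: fit each single drug,
test pairwise parallelism, gate the requested ratio, compute the additive
mixture ED50, fit the mixture, compare, classify, and write structured
JSON records plus a run log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from . import __version__
from .doseresponse import (
    DoseGroup,
    FitConfig,
    ProbitFit,
    fit_log_probit,
    test_parallelism,
)
from .isobole import (
    MixtureED50,
    MixtureSpec,
    additive_mixture_ed50,
    compare_mixture_ed50,
    eligible_fixed_ratios,
    isobologram_projections,
)

__all__ = [
    "AnalysisConfig",
    "AnalysisError",
    "read_dose_groups",
    "write_dose_groups",
    "run_full_analysis",
    "fit_to_record",
]

logger = logging.getLogger("isobol")

_REQUIRED_COLUMNS = ["drug_id", "dose_mg_per_kg", "n_tested", "n_protected"]


class AnalysisError(RuntimeError):
    """A pipeline stage failed; partial artifacts are marked in the run log."""


def read_dose_groups(path: str | Path) -> list[DoseGroup]:
    """Read dose groups from delimiter-separated text (``,``, ``;`` or tab).

    Errors name the offending data row (1-based, excluding the header).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python", encoding="utf-8")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    groups: list[DoseGroup] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            pre = getattr(row, "pretreatment_min", None)
            if pre is not None and (isinstance(pre, float) and math.isnan(pre)):
                pre = None
            groups.append(
                DoseGroup(
                    drug_id=str(row.drug_id),
                    dose=float(row.dose_mg_per_kg),
                    n_tested=int(row.n_tested),
                    n_protected=int(row.n_protected),
                    pretreatment_min=float(pre) if pre is not None else None,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: row {row_no}: {exc}") from exc
    return groups


def write_dose_groups(groups: Sequence[DoseGroup], path: str | Path) -> None:
    """Write dose groups as CSV; round-trips exactly through read_dose_groups."""
    rows = []
    for g in groups:
        row = {
            "drug_id": g.drug_id,
            "dose_mg_per_kg": g.dose,
            "n_tested": g.n_tested,
            "n_protected": g.n_protected,
        }
        if g.pretreatment_min is not None:
            row["pretreatment_min"] = g.pretreatment_min
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def fit_to_record(fit: ProbitFit) -> dict:
    """JSON-ready summary of one probit fit."""
    return {
        "drug_id": fit.drug_id,
        "ed50": fit.ed50,
        "sem_ed50": fit.sem_ed50,
        "slope": fit.slope,
        "intercept": fit.intercept,
        "log_ed50": fit.log_ed50,
        "sem_log_ed50": fit.sem_log_ed50,
        "n_total": fit.n_total,
        "df": fit.df,
        "converged": fit.converged,
        "loglik": fit.loglik,
        "engine": fit.engine,
    }


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of a full fixed-ratio analysis run."""

    single_inputs: tuple[str, ...]  # one dose-group file per single drug
    mixture_input: str  # dose-group file for the mixture (total doses)
    drug_ids: tuple[str, ...]  # mixture components, ordered
    ratio: str = "1:1:1"
    alpha: float = 0.05
    df: int | None = None  # t-test df; None -> animals-based rule
    fit: FitConfig = FitConfig()
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Execute the complete analysis and write result artifacts.

    Stages: fit singles -> pairwise parallelism -> fixed-ratio eligibility
    gate (warn-and-proceed when the requested ratio is ineligible) ->
    additive ED50 -> fit mixture -> t comparison -> classification.
    Writes ``analysis.json`` (all records, full precision) and
    ``run.log`` under ``config.out_dir``; returns the record dict.

    Raises :class:`AnalysisError` on any stage failure after writing the
    partial artifacts collected so far, marked ``"status": "failed"``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    record: dict = {
        "tool": "isobol",
        "version": __version__,
        "seed": config.seed,
        "config": {
            **{
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k not in ("fit",)
            },
            "fit": dataclasses.asdict(config.fit),
        },
        "status": "failed",
    }
    try:
        record["input_checksums"] = {
            str(p): _sha256(Path(p))
            for p in [*config.single_inputs, config.mixture_input]
        }
        logger.info("config: %s", json.dumps(record["config"]))

        spec = MixtureSpec.from_ratio(config.drug_ids, config.ratio)

        fits: dict[str, ProbitFit] = {}
        for path in config.single_inputs:
            groups = read_dose_groups(path)
            by_drug: dict[str, list[DoseGroup]] = {}
            for g in groups:
                by_drug.setdefault(g.drug_id, []).append(g)
            for drug, gs in by_drug.items():
                fit = fit_log_probit(gs, config.fit)
                if not fit.converged:
                    raise AnalysisError(f"probit fit for {drug} did not converge")
                fits[drug] = fit
                logger.info(
                    "fit %s: ED50 %.2f +/- %.2f mg/kg, slope %.2f",
                    drug, fit.ed50, fit.sem_ed50, fit.slope,
                )
        missing = [d for d in config.drug_ids if d not in fits]
        if missing:
            raise AnalysisError(f"no dose groups found for component(s) {missing}")
        record["fits"] = [fit_to_record(fits[d]) for d in config.drug_ids]

        parallelism = {
            (a, b): test_parallelism(fits[a], fits[b], alpha=config.alpha)
            for a, b in combinations(config.drug_ids, 2)
        }
        record["parallelism"] = [
            {
                "pair": [a, b],
                "statistic": r.statistic,
                "p_value": r.p_value,
                "parallel": r.parallel,
                "slope_ratio": r.slope_ratio,
            }
            for (a, b), r in parallelism.items()
        ]
        policy = eligible_fixed_ratios(parallelism, config.drug_ids)
        record["ratio_policy"] = {
            "all_parallel": policy.all_parallel,
            "eligible": policy.eligible,
            "reason": policy.reason,
        }
        if not policy.allows(spec):
            logger.warning(
                "requested ratio %s is not isobolographically eligible (%s); "
                "proceeding anyway", config.ratio, policy.reason,
            )

        ordered_fits = [fits[d] for d in config.drug_ids]
        additive = additive_mixture_ed50(ordered_fits, spec)

        mix_groups = read_dose_groups(config.mixture_input)
        mix_ids = {g.drug_id for g in mix_groups}
        if len(mix_ids) > 1:
            # mixture rows may share a file with singles; pick the joined id
            joined = "+".join(config.drug_ids)
            candidates = mix_ids - set(config.drug_ids)
            if joined in mix_ids:
                mix_id = joined
            elif len(candidates) == 1:
                mix_id = candidates.pop()
            else:
                raise AnalysisError(
                    f"cannot identify the mixture rows among drug_ids {sorted(mix_ids)}"
                )
            mix_groups = [g for g in mix_groups if g.drug_id == mix_id]
        mix_fit = fit_log_probit(mix_groups, config.fit)
        if not mix_fit.converged:
            raise AnalysisError("mixture probit fit did not converge")
        record["mixture_fit"] = fit_to_record(mix_fit)
        comp = {
            d: mix_fit.ed50 * w / additive.total_ed50
            for d, w in additive.component_doses.items()
        }
        experimental = MixtureED50(
            kind="experimental",
            total_ed50=mix_fit.ed50,
            sem=mix_fit.sem_ed50,
            component_doses=comp,
            df=mix_fit.n_total,
        )
        for mix, name in ((additive, "additive"), (experimental, "experimental")):
            record[name] = {
                "total_ed50": mix.total_ed50,
                "sem": mix.sem,
                "component_doses": mix.component_doses,
                "df": mix.df,
            }
            logger.info(
                "%s mixture ED50: %.2f +/- %.2f mg/kg", name, mix.total_ed50, mix.sem
            )

        interaction = compare_mixture_ed50(
            experimental,
            additive,
            alpha=config.alpha,
            df=config.df,
            df_policy="explicit" if config.df is not None else "animals",
        )
        record["interaction"] = {
            "t_statistic": interaction.t_statistic,
            "df": interaction.df,
            "p_value": interaction.p_value,
            "alpha": interaction.alpha,
            "interaction_index": interaction.interaction_index,
            "classification": interaction.classification,
        }
        record["projections"] = {
            f"{x}|{y}": panels
            for (x, y), panels in isobologram_projections(
                experimental, additive
            ).items()
        }
        logger.info(
            "interaction: t=%.3f df=%d p=%.4f index=%.3f -> %s",
            interaction.t_statistic,
            interaction.df,
            interaction.p_value,
            interaction.interaction_index,
            interaction.classification,
        )
        record["status"] = "ok"
        return record
    finally:
        (out_dir / "analysis.json").write_text(json.dumps(record, indent=2))
        logger.removeHandler(handler)
        handler.close()
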