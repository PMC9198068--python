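"""Validation of the index: caseload association, leave-one-indicator-out
robustness, and recovery of synthetic truth.

The epidemiological check correlates regional index values with regional
cumulative caseloads — a positive rank correlation is the qualitative
signature that the index flags transmission hotspots.  The robustness check
refits the PCA on every four-indicator subset and correlates the reduced
scores with the full five-indicator scores; a composite index dominated by
no single input keeps these correlations high.  On synthetic data the
latent regional deprivation is known, so recovery can be measured directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SchemaError
from .indicators import INDICATOR_COLUMNS
from .pca import fit_pdi_model, score_households

logger = logging.getLogger(__name__)


@dataclass
class ValidationReport:
    pearson: float
    spearman: float
    n_regions: int
    loo_correlations: dict[str, float] = field(default_factory=dict)
    truth_spearman: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [("pearson_caseload", self.pearson),
                ("spearman_caseload", self.spearman),
                ("n_regions", self.n_regions)]
        rows += [(f"loo_excluding_{k}", v) for k, v in self.loo_correlations.items()]
        if self.truth_spearman is not None:
            rows.append(("spearman_truth", self.truth_spearman))
        return pd.DataFrame(rows, columns=["metric", "value"])


def correlate_with_caseload(
    aggregates: pd.DataFrame,
    caseloads: pd.DataFrame,
    method: str = "pearson",
    per_capita: bool = False,
    population: pd.DataFrame | None = None,
) -> tuple[float, int]:
    """Correlation between normalized regional index and cumulative caseload.

    Regions are matched on region_id; unmatched ones are logged and
    excluded.  ``per_capita`` divides caseloads by a population column
    (region_id, population) before correlating.
    """
    if method not in ("pearson", "spearman"):
        raise SchemaError(f"unknown correlation method {method!r}")
    merged = aggregates[["region_id", "pdi_normalized"]].merge(
        caseloads[["region_id", "cumulative_cases"]], on="region_id", how="inner"
    )
    n_unmatched = len(aggregates) + len(caseloads) - 2 * len(merged)
    if n_unmatched:
        logger.warning("%d regions unmatched between aggregates and caseloads",
                       n_unmatched)
    if len(merged) < 3:
        raise SchemaError(
            f"only {len(merged)} matched regions; at least 3 needed for a correlation"
        )
    cases = merged["cumulative_cases"].to_numpy(float)
    if per_capita:
        if population is None:
            raise SchemaError("per_capita requested but no population table given")
        pop = merged[["region_id"]].merge(population, on="region_id")["population"]
        cases = cases / pop.to_numpy(float)
    if method == "pearson":
        r = stats.pearsonr(merged["pdi_normalized"], cases).statistic
    else:
        r = stats.spearmanr(merged["pdi_normalized"], cases).statistic
    return float(r), len(merged)


def leave_one_out_index(matrix: np.ndarray) -> dict[str, float]:
    """Refit the PCA excluding each indicator in turn.

    Returns, per excluded indicator (canonical order), the Pearson
    correlation between the reduced four-indicator scores and the full
    five-indicator scores.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[1] != len(INDICATOR_COLUMNS):
        raise SchemaError("leave-one-out expects the full five-indicator matrix")
    full = score_households(fit_pdi_model(X), X)
    out: dict[str, float] = {}
    for j, name in enumerate(INDICATOR_COLUMNS):
        keep = [k for k in range(X.shape[1]) if k != j]
        sub = X[:, keep]
        sub_names = tuple(INDICATOR_COLUMNS[k] for k in keep)
        model = fit_pdi_model(sub, feature_names=sub_names)
        reduced = score_households(model, sub)
        out[name] = float(stats.pearsonr(full, reduced).statistic)
    return out


def recover_truth(aggregates: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Spearman correlation of the normalized regional index with the true
    latent regional deprivation (synthetic data only)."""
    merged = aggregates[["region_id", "pdi_normalized"]].merge(
        truth[["region_id", "true_deprivation"]], on="region_id", how="inner"
    )
    if len(merged) < 3:
        raise SchemaError(
            f"only {len(merged)} matched regions; at least 3 needed"
        )
    return float(stats.spearmanr(
        merged["pdi_normalized"], merged["true_deprivation"]).statistic)


def build_report(
    aggregates: pd.DataFrame,
    caseloads: pd.DataFrame | None = None,
    matrix: np.ndarray | None = None,
    truth: pd.DataFrame | None = None,
) -> ValidationReport:
    """Assemble the standard validation report from available inputs."""
    pearson = spearman = np.nan
    n = 0
    if caseloads is not None:
        pearson, n = correlate_with_caseload(aggregates, caseloads, "pearson")
        spearman, _ = correlate_with_caseload(aggregates, caseloads, "spearman")
    loo = leave_one_out_index(matrix) if matrix is not None else {}
    truth_rho = recover_truth(aggregates, truth) if truth is not None else None
    return ValidationReport(
        pearson=float(pearson), spearman=float(spearman), n_regions=int(n),
        loo_correlations=loo, truth_spearman=truth_rho,
    )
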