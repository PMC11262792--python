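"""Cohort screening layer: expression filters, trait/T2D models, candidate rules.

The screen regresses each metabolic response on one miRNA at a time with
the histological and demographic covariates held in the design:

    trait or T2D = b0 + b1*NAS + b2*age + b3*sex + b4*BMI + b5*log2miRNA

Continuous traits use ordinary least squares, the binary T2D status a
logistic model; b5 is the effect of one log2 unit of miRNA expression and
its Wald p-value drives the association call (p < 0.05). Confounding by
age or BMI is probed with dedicated models

    age or BMI = b0 + b1*HbA1c + b3*sex + b4*[BMI or age] + b5*log2miRNA

and a candidate miRNA must be confidently expressed, associated with at
least two responses, free of age/BMI association, and (optionally)
seed-conserved across species. q-values (Benjamini-Hochberg, family = one
response across all tested miRNAs) are reported alongside the raw p-values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import SingularDesignError, ValidationError

#: design covariates, in the order of the model formula
COVARIATES = ("NAS", "age", "sex", "BMI")
#: responses screened by default (T2D is the binary one)
DEFAULT_RESPONSES = ("T2D", "HbA1c", "glucose", "NAS", "insulin", "triglycerides")
EXPRESSION_THRESHOLD = 2.3
ALPHA = 0.05


@dataclass(frozen=True)
class AssociationResult:
    """Fit summary for one (miRNA, response) pair."""

    mirna_id: str
    response: str
    model: str                      # "linear" | "logistic"
    betas: Mapping[str, float]
    p_value: float                  # Wald p for the miRNA coefficient (nan if not converged)
    n: int
    converged: bool
    q_value: float = math.nan

    @property
    def beta_mirna(self) -> float:
        return self.betas["log2miRNA"]

    def associated(self, alpha: float = ALPHA) -> bool:
        return self.converged and math.isfinite(self.p_value) and self.p_value < alpha


def dabg_filter(
    detection_p: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> set[str]:
    """Probesets detected above background.

    A probeset is kept iff strictly more than half of its probes have a
    detection p-value below *alpha*.
    """
    kept = set()
    for probeset, pvals in detection_p.items():
        pvals = list(pvals)
        if not pvals:
            raise ValidationError(f"probeset {probeset!r} has no probe p-values")
        if sum(p < alpha for p in pvals) > len(pvals) / 2:
            kept.add(probeset)
    return kept


def expression_filter(
    expr: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    threshold: float = EXPRESSION_THRESHOLD,
) -> set[str]:
    """miRNAs whose maximal group-mean log2 value exceeds *threshold* (strict >).

    *expr* is miRNAs x samples; *groups* maps sample id to group label.
    """
    groups = pd.Series(dict(groups))
    missing = [s for s in expr.columns if s not in groups.index]
    if missing:
        raise ValidationError(f"samples without group label: {missing[:5]}")
    labels = groups.loc[expr.columns]
    for g, cols in labels.groupby(labels).groups.items():
        if len(cols) == 0:  # pragma: no cover - defensive
            raise ValidationError(f"group {g!r} has no samples")
    group_means = expr.T.groupby(labels).mean().T
    return set(expr.index[(group_means.max(axis=1) > threshold)])


def _design(
    pheno: pd.DataFrame,
    expr_values: pd.Series,
    response: str,
    covariates: Sequence[str],
) -> tuple[pd.Series, pd.DataFrame]:
    cols = [c for c in covariates if c != response]
    missing = [c for c in cols + [response] if c not in pheno.columns]
    if missing:
        raise ValidationError(f"phenotype table lacks columns {missing}")
    df = pheno[[response] + cols].copy()
    df["log2miRNA"] = expr_values.reindex(df.index)
    df = df.dropna()
    y = df[response].astype(float)
    X = sm.add_constant(df[cols + ["log2miRNA"]].astype(float), has_constant="add")
    if len(df) < X.shape[1] + 1:
        raise ValidationError(
            f"only {len(df)} complete cases for {X.shape[1]} parameters"
        )
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise SingularDesignError(
            f"rank-deficient design for response {response!r} (constant column?)"
        )
    return y, X


def fit_trait_model(
    expr: pd.DataFrame,
    pheno: pd.DataFrame,
    mirna_id: str,
    response: str,
    covariates: Sequence[str] = COVARIATES,
) -> AssociationResult:
    """Fit the covariate-adjusted single-miRNA model for one response.

    Continuous responses use OLS; 'T2D' (binary) a logistic model fitted by
    Newton/IRLS (tol 1e-8, max 100 iterations). A response that is itself a
    covariate (e.g. NAS) is removed from the design. Non-convergence or
    perfect separation yields converged=False with p marked unavailable.
    """
    if mirna_id not in expr.index:
        raise ValidationError(f"unknown miRNA {mirna_id!r}")
    y, X = _design(pheno, expr.loc[mirna_id], response, covariates)
    logistic = set(np.unique(y)) <= {0.0, 1.0}
    if y.nunique() < 2:
        raise SingularDesignError(f"response {response!r} is constant across samples")
    if logistic:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
            converged = bool(res.mle_retvals.get("converged", False))
        except (PerfectSeparationError, np.linalg.LinAlgError):
            return AssociationResult(
                mirna_id=mirna_id, response=response, model="logistic",
                betas={c: math.nan for c in X.columns}, p_value=math.nan,
                n=len(y), converged=False,
            )
        model = "logistic"
    else:
        res = sm.OLS(y, X).fit()
        converged = True
        model = "linear"
    betas = {c: float(res.params[c]) for c in X.columns}
    p = float(res.pvalues["log2miRNA"]) if converged else math.nan
    return AssociationResult(
        mirna_id=mirna_id, response=response, model=model,
        betas=betas, p_value=p, n=int(len(y)), converged=converged,
    )


def confounder_check(
    expr: pd.DataFrame,
    pheno: pd.DataFrame,
    mirna_id: str,
    alpha: float = ALPHA,
) -> dict[str, bool]:
    """Flags for association of the miRNA with age and with BMI.

    Each confounder is modelled with HbA1c, sex and the other confounder as
    covariates; the flag is True iff the miRNA coefficient's p < *alpha*.
    """
    flags = {}
    for conf, other in (("age", "BMI"), ("BMI", "age")):
        res = fit_trait_model(
            expr, pheno, mirna_id, conf, covariates=("HbA1c", "sex", other)
        )
        flags[f"{conf.lower()}_associated"] = res.associated(alpha)
    return flags


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving per element."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_qvalues(results: Sequence[AssociationResult]) -> list[AssociationResult]:
    """q-values per response family across all converged results."""
    out = list(results)
    by_response: dict[str, list[int]] = {}
    for i, r in enumerate(out):
        if r.converged and math.isfinite(r.p_value):
            by_response.setdefault(r.response, []).append(i)
    for idxs in by_response.values():
        qs = bh_fdr([out[i].p_value for i in idxs])
        for i, q in zip(idxs, qs):
            r = out[i]
            out[i] = AssociationResult(
                mirna_id=r.mirna_id, response=r.response, model=r.model,
                betas=r.betas, p_value=r.p_value, n=r.n,
                converged=r.converged, q_value=float(q),
            )
    return out


@dataclass
class CandidateReport:
    """Per-miRNA outcome of the candidate selection rules."""

    table: pd.DataFrame
    alpha: float
    min_associations: int
    require_conserved: bool

    @property
    def candidates(self) -> list[str]:
        return list(self.table.index[self.table["candidate"]])


def select_candidates(
    results: Sequence[AssociationResult],
    confounders: Mapping[str, Mapping[str, bool]],
    expressed: Iterable[str],
    conserved: Optional[Iterable[str]] = None,
    alpha: float = ALPHA,
    min_associations: int = 2,
    require_conserved: bool = True,
    require_t2d: bool = False,
    responses: Sequence[str] = DEFAULT_RESPONSES,
) -> CandidateReport:
    """Apply the exclusion rules that define a candidate miRNA.

    candidate <=> confidently expressed AND >= *min_associations* response
    associations (raw p < alpha; non-converged fits never count) AND no
    age/BMI association AND (if *require_conserved*) seed-conserved.
    *require_t2d* additionally demands T2D among the associated responses.
    """
    expressed = set(expressed)
    conserved_set = set(conserved) if conserved is not None else None
    mirnas = sorted({r.mirna_id for r in results})
    assoc_map: dict[str, list[str]] = {m: [] for m in mirnas}
    for r in results:
        if r.response in responses and r.associated(alpha):
            assoc_map[r.mirna_id].append(r.response)
    rows = []
    for m in mirnas:
        traits = sorted(set(assoc_map[m]))
        flags = confounders.get(m, {})
        age_f = bool(flags.get("age_associated", False))
        bmi_f = bool(flags.get("bmi_associated", False))
        cons = True if conserved_set is None else m in conserved_set
        cand = (
            m in expressed
            and len(traits) >= min_associations
            and not age_f
            and not bmi_f
            and (cons or not require_conserved)
            and (not require_t2d or "T2D" in traits)
        )
        rows.append(
            {
                "mirna_id": m,
                "passed_expression": m in expressed,
                "associated_traits": ",".join(traits),
                "n_associated": len(traits),
                "age_associated": age_f,
                "bmi_associated": bmi_f,
                "conserved": cons,
                "candidate": cand,
            }
        )
    table = pd.DataFrame(rows).set_index("mirna_id")
    return CandidateReport(
        table=table, alpha=alpha, min_associations=min_associations,
        require_conserved=require_conserved,
    )


def association_screen(
    expr: pd.DataFrame,
    pheno: pd.DataFrame,
    responses: Sequence[str] = DEFAULT_RESPONSES,
    mirnas: Optional[Sequence[str]] = None,
    alpha: float = ALPHA,
) -> tuple[list[AssociationResult], dict[str, dict[str, bool]]]:
    """Fit every (miRNA, response) model plus confounder checks.

    Returns the q-value-annotated results and the per-miRNA confounder
    flags. Degenerate fits (constant miRNA etc.) are skipped with a warning
    rather than aborting the screen.
    """
    mirnas = list(mirnas) if mirnas is not None else list(expr.index)
    results: list[AssociationResult] = []
    confounders: dict[str, dict[str, bool]] = {}
    for m in mirnas:
        try:
            confounders[m] = confounder_check(expr, pheno, m, alpha=alpha)
            for resp in responses:
                results.append(fit_trait_model(expr, pheno, m, resp))
        except SingularDesignError as exc:
            warnings.warn(f"skipping miRNA {m!r}: {exc}")
            confounders.pop(m, None)
            results = [r for r in results if r.mirna_id != m]
    return attach_qvalues(results), confounders


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "mirna_id": r.mirna_id, "response": r.response, "model": r.model,
            "beta_mirna": r.beta_mirna, "p_value": r.p_value,
            "q_value": r.q_value, "n": r.n, "converged": r.converged,
        }
        rows.append(row)
    return pd.DataFrame(rows)
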