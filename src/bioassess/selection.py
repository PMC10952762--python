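"""Stepwise driver selection, window profiles and variance partitioning.

Model search follows the Schwarz Bayesian information criterion in its
Gaussian-likelihood form

    BIC = n * ln(SSE / n) + k * ln(n)

with k the number of estimated coefficients including the intercept.  The
search is forward selection with backward elimination: at each step the
term whose inclusion most decreases BIC enters, then single-term removals
are tested; the search stops when no move decreases BIC.  Structural terms
(site, sampling occasion) are offered alongside the hydrochemical
candidates as fixed-effect dummy blocks — a fixed-effects approximation to
a replicate-nested covariance structure, with replicates kept as rows.

Candidates are z-standardised before selection so every summary statistic
enters on an equal footing; ties in BIC break lexicographically by term
name, making the search deterministic.

Variance partitioning uses sequential (type-I) sums of squares entered in
the order covariate -> site -> occasion-within-site -> residual, so the
chosen covariate is credited first.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .design import ID_COLUMNS, parse_candidate_name
from .types import SelectionResult, VariancePartition

__all__ = ["fit_and_score", "stepwise_select", "single_determinand_scan",
           "window_profile", "partition_variance", "structural_term_blocks"]

_SSE_FLOOR = 1e-12


def fit_and_score(
    X: np.ndarray, y: np.ndarray,
) -> tuple[np.ndarray, float, float, float, int]:
    """OLS fit returning (beta, SSE, BIC, R^2, rank).

    ``X`` must already include an intercept column.  Rank-deficient designs
    are fitted with the pseudo-inverse; ``k`` in the BIC counts only the
    estimated (non-aliased) coefficients.  A perfectly fitting model is
    guarded with a small SSE floor; a constant response reports R^2 = 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient design: aliased term(s) dropped from "
                      "the coefficient count", stacklevel=2)
    resid = y - X @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    bic = n * np.log(max(sse, _SSE_FLOOR) / n) + rank * np.log(n)
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return beta, sse, float(bic), float(max(0.0, min(1.0, r2))), int(rank)


def structural_term_blocks(
    design: pd.DataFrame,
    site_column: str = "site_id",
    occasion_column: str = "occasion",
) -> dict[str, np.ndarray]:
    """Fixed-effect dummy blocks for the structural terms.

    ``site``: one dummy per site beyond the first; ``occasion``: one dummy
    per sampling occasion beyond the first.  Replicates stay as rows.
    """
    blocks = {}
    for name, col in (("site", site_column), ("occasion", occasion_column)):
        if col in design.columns and design[col].nunique() > 1:
            blocks[name] = pd.get_dummies(
                design[col], drop_first=True).to_numpy(float)
    return blocks


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _candidate_columns(design: pd.DataFrame) -> list[str]:
    return [c for c in design.columns if c not in ID_COLUMNS]


def _complete_cases(
    design: pd.DataFrame, response: np.ndarray, candidates: list[str],
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Common complete-case rows across the response and all candidates.

    Candidates that would eliminate most rows are better dropped upstream
    (``build_design_matrix``); here any candidate with missing values on
    the response-complete rows is excluded so that every fitted model sees
    the same rows and BIC values stay comparable.
    """
    ok = np.isfinite(response)
    kept = [c for c in candidates
            if np.isfinite(design[c].to_numpy(float)[ok]).all()]
    sub = design.loc[ok].reset_index(drop=True)
    return sub, response[ok], kept


def stepwise_select(
    design: pd.DataFrame,
    response: np.ndarray | pd.Series,
    response_name: str = "response",
    candidates: list[str] | None = None,
    structural_terms: dict[str, np.ndarray] | None = None,
    include_structural: bool = True,
    standardize: bool = True,
) -> SelectionResult:
    """Forward-with-backward-elimination BIC search over candidate terms.

    Returns the selected term names in entry order, the BIC after each
    accepted step (non-increasing), the final R^2 and coefficients.  The
    result is deterministic given the input: candidate order never matters
    because ties break by term name.
    """
    response = np.asarray(response, dtype=float)
    if candidates is None:
        candidates = _candidate_columns(design)
    sub, y, kept = _complete_cases(design, response, candidates)
    n = len(y)

    terms: dict[str, np.ndarray] = {}
    for c in sorted(kept):
        x = sub[c].to_numpy(float)
        terms[c] = (_zscore(x) if standardize else x)[:, None]
    if include_structural:
        blocks = (structural_terms if structural_terms is not None
                  else structural_term_blocks(sub))
        terms.update(blocks)

    selected: list[str] = []
    X = np.ones((n, 1))
    _, sse, bic, _, rank = fit_and_score(X, y)
    bic_trace = [bic]

    def bic_of(names: list[str]) -> float:
        cols = [np.ones((n, 1))] + [terms[t] for t in names]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # aliasing expected while searching
            _, _, b, _, _ = fit_and_score(np.column_stack(cols), y)
        return b

    while True:
        moved = False
        # forward: best single addition; sorted iteration + strict
        # improvement means the lexicographically first of any tie wins
        best_add, best_add_bic = None, bic
        for name in sorted(set(terms) - set(selected)):
            b = bic_of(selected + [name])
            if b < best_add_bic - 1e-12:
                best_add, best_add_bic = name, b
        if best_add is not None:
            selected.append(best_add)
            bic = best_add_bic
            bic_trace.append(bic)
            moved = True
            # backward: drop any term whose removal decreases BIC
            improved = True
            while improved and len(selected) > 1:
                improved = False
                best_drop, best_drop_bic = None, bic
                for name in sorted(selected[:-1]):
                    b = bic_of([t for t in selected if t != name])
                    if b < best_drop_bic - 1e-12:
                        best_drop, best_drop_bic = name, b
                if best_drop is not None:
                    selected.remove(best_drop)
                    bic = best_drop_bic
                    bic_trace.append(bic)
                    improved = True
        if not moved:
            break

    cols = [np.ones((n, 1))] + [terms[t] for t in selected]
    beta, sse, bic_final, r2, rank = fit_and_score(np.column_stack(cols), y)
    coef: dict[str, float] = {"intercept": float(beta[0])}
    i = 1
    for t in selected:
        width = terms[t].shape[1]
        if width == 1:
            coef[t] = float(beta[i])
        else:
            for j in range(width):
                coef[f"{t}[{j}]"] = float(beta[i + j])
        i += width
    return SelectionResult(
        response=response_name, selected_terms=selected,
        bic_trace=bic_trace, r_squared=r2, coefficients=coef, n_obs=n)


def single_determinand_scan(
    design: pd.DataFrame,
    response: np.ndarray | pd.Series,
    putative_determinand: str | None = None,
    candidates: list[str] | None = None,
) -> pd.DataFrame:
    """R^2 of each candidate fitted alone against the response.

    Returns a frame ranked by R^2 (ties broken by candidate name) with a
    ``best_of_putative`` marker on the top candidate of the stated
    putative-stressor determinand, when one is given.
    """
    response = np.asarray(response, dtype=float)
    if candidates is None:
        candidates = _candidate_columns(design)
    ok = np.isfinite(response)
    rows = []
    for c in sorted(candidates):
        x = design[c].to_numpy(float)
        use = ok & np.isfinite(x)
        if use.sum() < 3 or x[use].std() == 0:
            continue
        X = np.column_stack([np.ones(use.sum()), x[use]])
        _, _, _, r2, _ = fit_and_score(X, y=response[use])
        det, stat, wind = parse_candidate_name(c)
        rows.append({"candidate": c, "determinand": det, "statistic": stat,
                     "window_days": wind, "r2": r2})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out = out.sort_values(["r2", "candidate"],
                          ascending=[False, True]).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    if putative_determinand is not None:
        mask = out["determinand"] == putative_determinand
        out["best_of_putative"] = False
        if mask.any():
            out.loc[out[mask].index[0], "best_of_putative"] = True
    return out


def window_profile(
    design: pd.DataFrame,
    response: np.ndarray | pd.Series,
    determinand: str,
    statistic: str,
) -> pd.DataFrame:
    """Single-candidate R^2 as a function of antecedent window length.

    Returns one row per available window for (determinand, statistic),
    with ``argmax`` marking the best window.
    """
    from .design import candidate_name

    response = np.asarray(response, dtype=float)
    rows = []
    available = [c for c in _candidate_columns(design)
                 if parse_candidate_name(c)[:2] == (determinand, statistic)]
    for c in sorted(available, key=lambda c: parse_candidate_name(c)[2]):
        _, _, wind = parse_candidate_name(c)
        x = design[c].to_numpy(float)
        use = np.isfinite(response) & np.isfinite(x)
        if use.sum() < 3 or x[use].std() == 0:
            r2 = 0.0
        else:
            X = np.column_stack([np.ones(use.sum()), x[use]])
            _, _, _, r2, _ = fit_and_score(X, response[use])
        rows.append({"determinand": determinand, "statistic": statistic,
                     "window_days": wind, "r2": r2})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["argmax"] = False
        out.loc[out["r2"].idxmax(), "argmax"] = True
    return out


def partition_variance(
    design: pd.DataFrame,
    response: np.ndarray | pd.Series,
    covariate: str,
    site_column: str = "site_id",
    occasion_column: str = "occasion",
) -> VariancePartition:
    """Hierarchical nested ANOVA variance partition (sequential type-I SS).

    Terms enter in the order covariate -> site -> occasion-within-site;
    shares are incremental explained SS over the total SS, with the
    remainder residual.  The covariate is credited first, so shared
    covariate/site variance counts toward the covariate.
    """
    response = np.asarray(response, dtype=float)
    x = design[covariate].to_numpy(float)
    ok = np.isfinite(response) & np.isfinite(x)
    sub = design.loc[ok]
    y = response[ok]
    x = x[ok]
    n = len(y)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        return VariancePartition(shares={"covariate": 0.0, "site": 0.0,
                                         "temporal": 0.0, "residual": 1.0})

    site = pd.get_dummies(sub[site_column], drop_first=True).to_numpy(float)
    cell = pd.get_dummies(
        sub[site_column].astype(str) + "/" + sub[occasion_column].astype(str),
        drop_first=True).to_numpy(float)

    ones = np.ones((n, 1))
    designs = [
        np.column_stack([ones, x]),
        np.column_stack([ones, x, site]),
        np.column_stack([ones, x, site, cell]),
    ]
    sse_prev = sst
    explained = []
    for X in designs:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # aliasing is expected here
            _, sse, _, _, _ = fit_and_score(X, y)
        explained.append(max(0.0, sse_prev - sse))
        sse_prev = sse
    residual = max(0.0, sse_prev)
    shares = {
        "covariate": explained[0] / sst,
        "site": explained[1] / sst,
        "temporal": explained[2] / sst,
        "residual": residual / sst,
    }
    total = sum(shares.values())
    shares = {k: v / total for k, v in shares.items()}
    return VariancePartition(shares=shares)
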