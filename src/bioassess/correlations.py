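"""Correlation structure of candidate drivers and of biotic indices.

Two complementary views of the candidate summary statistics are computed:
within a determinand across window lengths (how stable each statistic is
as the antecedent period grows), and within a window across determinands
(which determinands co-vary).  Per-determinand-pair averages condense the
latter into a single table.

Inter-index relationships are assessed with Gaussian identity-link linear
models with and without an additive site term, giving the pooled slope and
correlation, an F-test for site influence, and the within-site versus
among-site correlations.
"""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import ID_COLUMNS, parse_candidate_name

__all__ = ["pearson_pairwise", "average_correlations",
           "index_pairwise_relationships"]

AXES = ("within_determinand_across_windows",
        "within_window_across_determinands")


def _pairs_for_axis(columns: list[str], axis: str):
    parsed = {c: parse_candidate_name(c) for c in columns}
    if axis == "within_determinand_across_windows":
        keyfun = lambda c: parsed[c][0]
    elif axis == "within_window_across_determinands":
        keyfun = lambda c: parsed[c][2]
    else:
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
    groups: dict[object, list[str]] = {}
    for c in columns:
        groups.setdefault(keyfun(c), []).append(c)
    for _, cols in sorted(groups.items(), key=lambda kv: str(kv[0])):
        yield from itertools.combinations(sorted(cols), 2)


def pearson_pairwise(
    design: pd.DataFrame, axis: str, min_n: int = 3,
) -> pd.DataFrame:
    """Complete-case Pearson r for every candidate pair along an axis.

    Returns a tidy frame (col_a, col_b, r, n, flag); pairs with fewer than
    ``min_n`` complete rows or a zero-variance member get missing r and a
    flag.  Row order of the input never affects the result.
    """
    candidates = [c for c in design.columns if c not in ID_COLUMNS]
    records = []
    values = {c: design[c].to_numpy(dtype=float) for c in candidates}
    for a, b in _pairs_for_axis(candidates, axis):
        xa, xb = values[a], values[b]
        ok = np.isfinite(xa) & np.isfinite(xb)
        n = int(ok.sum())
        flag = ""
        if n < min_n:
            r = np.nan
            flag = f"fewer than {min_n} complete rows"
        else:
            sa, sb = xa[ok].std(), xb[ok].std()
            if sa == 0 or sb == 0:
                r = np.nan
                flag = "zero-variance column"
            else:
                r = float(np.corrcoef(xa[ok], xb[ok])[0, 1])
        records.append({"col_a": a, "col_b": b, "r": r, "n": n, "flag": flag})
    return pd.DataFrame(records)


def average_correlations(pairwise: pd.DataFrame) -> pd.DataFrame:
    """Mean r per determinand pair over matched (statistic, window) combos.

    Only pairs where the two columns share statistic and window (so the
    correlation isolates the determinands) are averaged; missing r values
    are excluded.  Returns a tidy frame (det_a, det_b, mean_r, n_pairs).
    """
    rows = []
    for rec in pairwise.itertuples(index=False):
        da, sa, wa = parse_candidate_name(rec.col_a)
        db, sb, wb = parse_candidate_name(rec.col_b)
        if da != db and sa == sb and wa == wb and np.isfinite(rec.r):
            pair = tuple(sorted((da, db)))
            rows.append({"det_a": pair[0], "det_b": pair[1], "r": rec.r})
    if not rows:
        return pd.DataFrame(columns=["det_a", "det_b", "mean_r", "n_pairs"])
    frame = pd.DataFrame(rows)
    out = (frame.groupby(["det_a", "det_b"], as_index=False)
           .agg(mean_r=("r", "mean"), n_pairs=("r", "size")))
    return out


def index_pairwise_relationships(
    index_table: pd.DataFrame,
    index_columns: list[str] | None = None,
    site_column: str = "site_id",
) -> pd.DataFrame:
    """Linear relationships between every pair of biotic indices.

    For each ordered-by-name pair (x, y): the pooled slope and Pearson r;
    an F-test of an additive site term (does the x-y relationship shift
    among sites?); the within-site r (correlation of residuals from site
    means) and the among-site r (correlation of site means).
    """
    if index_columns is None:
        index_columns = [c for c in index_table.columns
                         if index_table[c].dtype.kind == "f"]
    records = []
    for x_col, y_col in itertools.combinations(sorted(index_columns), 2):
        sub = index_table[[x_col, y_col, site_column]].dropna()
        sites = sub[site_column]
        if sites.nunique() < 2 or sub.groupby(site_column).size().min() < 3:
            continue
        x = sub[x_col].to_numpy(float)
        y = sub[y_col].to_numpy(float)
        n = len(sub)
        if x.std() == 0 or y.std() == 0:
            continue  # a constant index carries no relationship

        slope, intercept, r_pooled, _, _ = sps.linregress(x, y)

        # site-adjusted model: y ~ x + C(site); F-test of the site block
        dummies = pd.get_dummies(sites, drop_first=True).to_numpy(float)
        X0 = np.column_stack([np.ones(n), x])
        X1 = np.column_stack([X0, dummies])
        sse0 = _sse(X0, y)
        sse1 = _sse(X1, y)
        df_site = dummies.shape[1]
        df_resid = n - X1.shape[1]
        if df_resid > 0 and sse1 > 0:
            f_stat = ((sse0 - sse1) / df_site) / (sse1 / df_resid)
            p_site = float(sps.f.sf(f_stat, df_site, df_resid))
        else:
            f_stat, p_site = np.nan, np.nan

        # within-site r: correlation after removing site means
        xd = x - sub.groupby(site_column)[x_col].transform("mean").to_numpy()
        yd = y - sub.groupby(site_column)[y_col].transform("mean").to_numpy()
        r_within = (float(np.corrcoef(xd, yd)[0, 1])
                    if xd.std() > 0 and yd.std() > 0 else np.nan)
        means = sub.groupby(site_column)[[x_col, y_col]].mean()
        r_among = (float(np.corrcoef(means[x_col], means[y_col])[0, 1])
                   if len(means) > 2 and means[x_col].std() > 0
                   and means[y_col].std() > 0 else np.nan)

        records.append({
            "index_x": x_col, "index_y": y_col, "n": n,
            "slope": float(slope), "intercept": float(intercept),
            "r_pooled": float(r_pooled), "f_site": float(f_stat),
            "p_site": p_site, "r_within_site": r_within,
            "r_among_site": r_among,
        })
    return pd.DataFrame(records)


def _sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)
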