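"""Microarray significance filter.

Takes a processed (log2, normalized) expression matrix for a two-condition,
triplicate design and applies the fold-change/FDR gate used to define the
glucocorticoid-regulated gene list: per-probeset log2 fold change and Welch
two-sample test, Storey q-values (fixed-lambda pi0 estimate), selection at
|FC| >= 1.5 and q < 0.05, and probeset -> gene collapse keeping the probeset
with the largest |log2FC| per gene.

The differential test is a plain Welch t; users with a moderated-t analysis
(e.g. limma) can supply its output directly via a precomputed differential
table (``probeset, log2fc, p``) and still use the q-value/selection/collapse
steps.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FOLD_CHANGE_THRESHOLD",
    "Q_THRESHOLD",
    "read_expression",
    "signed_fold_change",
    "differential_table",
    "storey_qvalue",
    "select_regulated",
    "collapse_probesets",
    "regulation_counts",
]

FOLD_CHANGE_THRESHOLD = 1.5
Q_THRESHOLD = 0.05


def read_expression(
    matrix_tsv: str | Path, sample_sheet_csv: str | Path
) -> tuple[pd.DataFrame, pd.Series]:
    """Load a probesets x samples log2 matrix and its sample -> condition map."""
    mat = pd.read_csv(matrix_tsv, sep="\t", index_col=0, comment="#")
    sheet = pd.read_csv(sample_sheet_csv, comment="#")
    conditions = pd.Series(sheet["condition"].to_numpy(), index=sheet["sample"])
    missing = set(mat.columns) - set(conditions.index)
    if missing:
        raise ValueError(f"samples without condition labels: {sorted(missing)}")
    return mat, conditions.loc[mat.columns]


def signed_fold_change(log2fc: np.ndarray) -> np.ndarray:
    """Signed linear fold change: 2**lfc for lfc >= 0, else -2**(-lfc)."""
    log2fc = np.asarray(log2fc, dtype=float)
    return np.where(log2fc >= 0, 2.0 ** log2fc, -(2.0 ** (-log2fc)))


def differential_table(
    matrix: pd.DataFrame,
    conditions: pd.Series,
    treated: str,
    vehicle: str,
) -> pd.DataFrame:
    """Per-probeset log2 fold change (treated - vehicle) and Welch p-value.

    Probesets with zero variance in both groups get p = 1 when the group
    means agree (flagged ``degenerate``) and p = 0 when they differ.
    """
    t_cols = conditions.index[conditions == treated]
    v_cols = conditions.index[conditions == vehicle]
    if len(t_cols) < 2 or len(v_cols) < 2:
        raise ValueError("need >=2 replicates per condition")
    if matrix.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    t = matrix[t_cols].to_numpy(dtype=float)
    v = matrix[v_cols].to_numpy(dtype=float)
    log2fc = t.mean(axis=1) - v.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-identical replicate values trip scipy's precision-loss warning
        warnings.simplefilter("ignore", RuntimeWarning)
        p = sps.ttest_ind(t, v, axis=1, equal_var=False).pvalue
    degenerate = (t.var(axis=1) == 0) & (v.var(axis=1) == 0)
    p = np.where(degenerate & (log2fc == 0), 1.0, p)
    p = np.where(degenerate & (log2fc != 0), 0.0, p)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame(
        {
            "probeset": matrix.index.to_numpy(),
            "log2fc": log2fc,
            "fold_change": signed_fold_change(log2fc),
            "p": p,
            "degenerate": degenerate,
        }
    )


def storey_qvalue(pvalues, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with the fixed-lambda pi0 estimator.

    pi0_hat = min(1, #{p > lam} / (m (1 - lam))); q for the i-th ordered
    p-value is min over j >= i of pi0_hat * m * p_(j) / j, clipped to [0, 1].
    With pi0_hat = 1 this reduces to Benjamini-Hochberg adjusted p-values.
    Input order is preserved.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    pi0 = min(1.0, float((p > lam).sum()) / (m * (1.0 - lam)))
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    bh = pi0 * m * p_sorted / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(bh[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def select_regulated(
    records: pd.DataFrame,
    fold_change: float = FOLD_CHANGE_THRESHOLD,
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Apply the significance gate: |FC| >= fold_change (inclusive) and
    q < q_threshold (strict). Adds ``significant`` and ``direction`` columns."""
    if "q" not in records:
        raise ValueError("records must carry q-values (run storey_qvalue first)")
    out = records.copy()
    out["significant"] = (out["fold_change"].abs() >= fold_change) & (
        out["q"] < q_threshold
    )
    out["direction"] = np.where(
        ~out["significant"], "none", np.where(out["log2fc"] > 0, "up", "down")
    )
    return out


def collapse_probesets(
    records: pd.DataFrame, probeset_map: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Collapse probeset records to one record per gene.

    *probeset_map* has columns ``probeset, gene_id``. Per gene the probeset
    with the largest |log2fc| represents the gene (its log2fc, p, q and
    direction carry over); a ``conflict`` flag marks genes whose probesets
    disagree in fold-change sign. Probesets absent from the map are excluded
    and returned as the second element.
    """
    mapping = probeset_map.set_index("probeset")["gene_id"]
    merged = records.copy()
    merged["gene_id"] = merged["probeset"].map(mapping)
    unmapped = merged.loc[merged["gene_id"].isna(), "probeset"].astype(str).tolist()
    merged = merged.dropna(subset=["gene_id"])
    rows = []
    for gene, sub in merged.groupby("gene_id", sort=True):
        rep = sub.loc[sub["log2fc"].abs().idxmax()]
        signs = np.sign(sub["log2fc"].to_numpy())
        conflict = bool((signs > 0).any() and (signs < 0).any())
        row = {"gene_id": gene, "n_probesets": len(sub), "conflict": conflict}
        for col in ("probeset", "log2fc", "fold_change", "p", "q", "significant", "direction"):
            if col in sub:
                row[col] = rep[col]
        rows.append(row)
    return pd.DataFrame(rows), unmapped


def regulation_counts(selected: pd.DataFrame, probeset_map: pd.DataFrame | None = None) -> dict:
    """Up/down/total counts at probeset level and (with a map) gene level."""
    sig = selected[selected["significant"]]
    counts = {
        "n_significant_probesets": int(len(sig)),
        "n_up_probesets": int((sig["direction"] == "up").sum()),
        "n_down_probesets": int((sig["direction"] == "down").sum()),
    }
    if probeset_map is not None:
        genes, unmapped = collapse_probesets(sig, probeset_map)
        counts.update(
            {
                "n_genes": int(len(genes)),
                "n_up_genes": int((genes["direction"] == "up").sum()),
                "n_down_genes": int((genes["direction"] == "down").sum()),
                "n_unmapped_probesets": len(unmapped),
            }
        )
    return counts
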