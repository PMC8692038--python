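"""Expression (TPM) and proteome-composition profiling.

Reproduces the comparison logic used to contrast silk-gland expression and
dragline-silk protein composition between two samples/species: TPM
normalization of count tables, pseudocounted per-gene expression ratios,
and intensity-based proteome shares per protein family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = ["ExpressionTable", "ProteomeTable", "tpm", "expression_ratio",
           "proteome_shares"]


@dataclass
class ExpressionTable:
    """Per-gene counts, effective lengths, and TPM values."""
    rows: pd.DataFrame  # index: gene id; columns: est_count, effective_length, tpm

    def __getitem__(self, gene: str) -> float:
        return float(self.rows.loc[gene, "tpm"])

    @property
    def tpm(self) -> dict[str, float]:
        return self.rows["tpm"].to_dict()


@dataclass
class ProteomeTable:
    """Per-protein intensities with a family/group label."""
    rows: pd.DataFrame  # index: protein id; columns: intensity, group


def tpm(counts: dict[str, float], lengths: dict[str, float]) -> ExpressionTable:
    """Transcripts-per-million: rate_i = count_i/length_i,
    tpm_i = 1e6 * rate_i / sum(rate).  All-zero counts yield all-zero TPM."""
    if set(counts) != set(lengths):
        raise ValueError("counts and lengths must share the same gene ids")
    genes = sorted(counts)
    df = pd.DataFrame({
        "est_count": [float(counts[g]) for g in genes],
        "effective_length": [float(lengths[g]) for g in genes],
    }, index=genes)
    if (df["effective_length"] <= 0).any():
        raise ValueError("effective lengths must be strictly positive")
    if (df["est_count"] < 0).any():
        raise ValueError("counts must be nonnegative")
    rate = df["est_count"] / df["effective_length"]
    total = rate.sum()
    df["tpm"] = 0.0 if total == 0 else 1e6 * rate / total
    return ExpressionTable(rows=df)


def expression_ratio(a: ExpressionTable, b: ExpressionTable,
                     pseudocount: float = 0.5) -> dict[str, float]:
    """Per-gene (tpm_a + pseudocount) / (tpm_b + pseudocount) over the
    shared gene ids; genes absent from either table are omitted with a
    warning."""
    ta, tb = a.tpm, b.tpm
    shared = sorted(set(ta) & set(tb))
    missing = sorted(set(ta) ^ set(tb))
    if missing:
        warnings.warn(f"genes absent from one table omitted: {missing}",
                      stacklevel=2)
    return {g: (ta[g] + pseudocount) / (tb[g] + pseudocount) for g in shared}


def proteome_shares(table: ProteomeTable) -> dict[str, float]:
    """Intensity share per group: sum of group intensities over the total."""
    df = table.rows
    if (df["intensity"] < 0).any():
        raise ValueError("intensities must be nonnegative")
    total = df["intensity"].sum()
    if total == 0:
        raise ValueError("all intensities are zero")
    shares = df.groupby("group")["intensity"].sum() / total
    return {g: float(s) for g, s in shares.items()}
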