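"""Set-level analytics over per-condition enrichment tables.

Given one enrichment table per bait variant (and stimulation arm), these
operations compute the consensus "core" interactome (hits in at least k
conditions), strict and relaxed pairwise overlaps, phosphoprotein-bias
curves over fold-change thresholds, sub-proteome median shifts, the
distribution of hits over submitochondrial compartments, and overlap with a
reference interactor list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

COMPARTMENTS = ("matrix", "inner membrane", "intermembrane space",
                "outer membrane", "unknown")


@dataclass
class HitMatrix:
    """Boolean proteins x conditions membership matrix."""

    membership: pd.DataFrame  # bool, index=protein_id, columns=condition labels

    def __post_init__(self) -> None:
        if not self.membership.dtypes.map(lambda d: d == bool).all():
            self.membership = self.membership.astype(bool)

    @classmethod
    def from_tables(cls, tables: dict[str, pd.DataFrame]) -> "HitMatrix":
        """Assemble from per-condition enrichment tables (need a ``hit`` column).

        The protein universe is the union; proteins absent from a table are
        treated as non-hits there.
        """
        universe = sorted(set().union(*(set(t.index) for t in tables.values())))
        member = pd.DataFrame(False, index=universe, columns=list(tables))
        for label, t in tables.items():
            hits = t.index[t["hit"].astype(bool)]
            member.loc[member.index.isin(hits), label] = True
        return cls(member)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.membership.index)

    @property
    def condition_labels(self) -> list[str]:
        return list(self.membership.columns)


def core_interactome(hits: HitMatrix, k: int) -> set[str]:
    """Proteins called as hits in at least ``k`` conditions (row sum >= k)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    counts = hits.membership.sum(axis=1)
    return set(counts.index[counts >= k])


def strict_overlap(table_a: pd.DataFrame, table_b: pd.DataFrame) -> tuple[int, set[str]]:
    """Proteins that are strict hits (both cut-offs) in both tables."""
    if not set(table_a.index) & set(table_b.index):
        warnings.warn("tables share no proteins; overlap is empty")
        return 0, set()
    hits_a = set(table_a.index[table_a["hit"].astype(bool)])
    hits_b = set(table_b.index[table_b["hit"].astype(bool)])
    common = hits_a & hits_b
    return len(common), common


def relaxed_overlap(table_a: pd.DataFrame, table_b: pd.DataFrame,
                    p_cut: float = 0.05, fc_cut: float = 1.0) -> tuple[int, set[str]]:
    """Relaxed pairwise overlap (asymmetric in (a, b)).

    Both the p-value and fold-change cut-offs are applied to the first
    table, but only one of the two (at least one) needs to hold in the
    second. Always a superset of :func:`strict_overlap` at the same
    thresholds.
    """
    if not set(table_a.index) & set(table_b.index):
        warnings.warn("tables share no proteins; overlap is empty")
        return 0, set()
    hits_a = set(table_a.index[table_a["hit"].astype(bool)])
    pass_b = set(table_b.index[(table_b["p_value"] < p_cut)
                               | (table_b["log2_fc"] > fc_cut)])
    common = hits_a & pass_b
    return len(common), common


def _annotation_flags(annotation: pd.DataFrame, proteins, column: str) -> pd.Series:
    """Boolean flags for ``proteins``; absent proteins count as False."""
    flags = pd.Series(False, index=pd.Index(proteins))
    present = flags.index.intersection(annotation.index)
    flags.loc[present] = annotation.loc[present, column].astype(bool)
    return flags


def phosphoprotein_fraction_curve(table: pd.DataFrame, annotation: pd.DataFrame,
                                  thresholds) -> pd.DataFrame:
    """Fraction of phosphoproteins among proteins above each fold-change cut.

    For each threshold tau, the fraction of proteins with log2_fc > tau that
    are annotated phosphoproteins. Where no protein exceeds tau the fraction
    is undefined and emitted as NaN.
    """
    is_phospho = _annotation_flags(annotation, table.index, "is_phosphoprotein")
    rows = []
    fc = table["log2_fc"]
    for tau in thresholds:
        above = fc > tau
        denom = int(above.sum())
        frac = float(is_phospho[above].mean()) if denom else np.nan
        rows.append({"threshold": float(tau), "n_above": denom, "fraction": frac})
    return pd.DataFrame(rows)


def subproteome_median_shift(table: pd.DataFrame, annotation: pd.DataFrame,
                             flag: str = "is_mitochondrial") -> tuple[float, float, float]:
    """Median log2 fold-change of the whole table, of the flagged subset,
    and their difference (subset - whole)."""
    flags = _annotation_flags(annotation, table.index, flag)
    if not flags.any():
        raise ValueError(f"no proteins annotated {flag}")
    median_all = float(table["log2_fc"].median())
    median_sub = float(table.loc[flags.values, "log2_fc"].median())
    return median_all, median_sub, median_sub - median_all


def submito_distribution(hit_set, annotation: pd.DataFrame) -> dict[str, float]:
    """Fraction of mitochondrial hits per submitochondrial compartment.

    Fractions sum to 1 over the observed compartments (including
    ``unknown``). Hits absent from the annotation table are treated as
    non-mitochondrial.
    """
    if not hit_set:
        raise ValueError("hit set is empty")
    hits = pd.Index(sorted(hit_set))
    mito = _annotation_flags(annotation, hits, "is_mitochondrial")
    mito_hits = hits[mito.values]
    if len(mito_hits) == 0:
        warnings.warn("no mitochondrial hits; empty distribution")
        return {}
    comps = annotation.loc[annotation.index.intersection(mito_hits), "compartment"]
    comps = comps.reindex(mito_hits).fillna("unknown")
    frac = comps.value_counts(normalize=True)
    return {str(c): float(f) for c, f in frac.items()}


def reference_overlap(observed_proteins, hit_sets: dict[str, set],
                      annotation: pd.DataFrame) -> tuple[int, int, int]:
    """Overlap of the datasets with a reference interactor list.

    Returns (number of reference interactors, number of those observed in
    the datasets, number significant for at least one condition). The
    significant set is a subset of the observed set, which is a subset of
    the reference.
    """
    reference = set(annotation.index[annotation["is_reference_interactor"].astype(bool)])
    observed = reference & set(observed_proteins)
    any_hit = set().union(*hit_sets.values()) if hit_sets else set()
    significant = observed & any_hit
    return len(reference), len(observed), len(significant)


def read_annotation(path) -> pd.DataFrame:
    """Read an annotation TSV (protein_id, is_phosphoprotein,
    is_mitochondrial, compartment, is_reference_interactor)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    for col in ("is_phosphoprotein", "is_mitochondrial", "is_reference_interactor"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    if "compartment" in df.columns:
        df["compartment"] = df["compartment"].fillna("unknown")
    return df
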