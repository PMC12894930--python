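"""Bait-vs-control differential enrichment for proximity-labeling data.

The statistical model is deliberately simple, matching common practice for
TurboID/BioID hit calling: per protein group, a two-tailed heteroscedastic
(Welch) t-test on log2 intensities between bait and control replicates, a
log2 fold-change as the difference of mean log2 intensities, and a hit call
requiring jointly p < 0.05 and log2 fold-change > 1 (both strict). No
multiple-testing correction is applied by default because the hit rule
combines a raw p-value with a fold-change gate; an optional
Benjamini-Hochberg adjustment is available.

Bar-plot style summaries use the linear-scale ratio of means with a
first-order error-propagated standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

P_CUT = 0.05
FC_CUT = 1.0


def welch_t_test(group_a, group_b) -> float:
    """Two-tailed heteroscedastic (Welch) t-test p-value.

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with unbiased sample
    variances; degrees of freedom by Welch-Satterthwaite; two-tailed p from
    the t distribution.

    Degenerate conventions (both sample variances zero): p = 1 when the
    means are equal, p = 0 when they differ. These keep the test total on
    simulated data with constant groups.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t_test requires at least 2 values per group")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        return 1.0 if ma == mb else 0.0
    se2_a = va / a.size
    se2_b = vb / b.size
    t = (ma - mb) / np.sqrt(se2_a + se2_b)
    df = (se2_a + se2_b) ** 2 / (
        se2_a**2 / (a.size - 1) + se2_b**2 / (b.size - 1)
    )
    return float(2.0 * stats.t.sf(abs(t), df))


def log2_fold_change(log2_bait, log2_control) -> float:
    """mean(log2 bait) - mean(log2 control); inputs are log2-stage values."""
    a = np.asarray(log2_bait, dtype=float)
    b = np.asarray(log2_control, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("log2_fold_change requires nonempty groups")
    return float(a.mean() - b.mean())


def propagated_ratio_sd(bait, control) -> tuple[float, float]:
    """Ratio of means (linear scale) and its error-propagated SD.

    r = m_bait / m_control;
    sd(r) = |r| * sqrt((s_bait/m_bait)^2 + (s_control/m_control)^2).
    """
    a = np.asarray(bait, dtype=float)
    b = np.asarray(control, dtype=float)
    mb_, mc = a.mean(), b.mean()
    if mc == 0:
        raise ValueError("control mean is zero; ratio undefined")
    r = mb_ / mc
    sa = a.std(ddof=1) if a.size > 1 else 0.0
    sc = b.std(ddof=1) if b.size > 1 else 0.0
    rel_a = sa / mb_ if mb_ != 0 else 0.0
    rel_c = sc / mc
    return float(r), float(abs(r) * np.sqrt(rel_a**2 + rel_c**2))


def call_hits(table: pd.DataFrame, p_cut: float = P_CUT, fc_cut: float = FC_CUT) -> pd.DataFrame:
    """Flag hits: p_value < p_cut AND log2_fc > fc_cut, both strict."""
    out = table.copy()
    out["hit"] = (out["p_value"] < p_cut) & (out["log2_fc"] > fc_cut)
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional, off by default)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass
class EnrichmentResults:
    """Results of a bait-vs-control enrichment contrast.

    Attributes
    ----------
    table : pandas.DataFrame
        one row per protein with columns ``log2_fc``, ``p_value``, ``hit``,
        ``mean_ratio``, ``ratio_sd`` (index: protein_id).
    bait_label, control_label : str
    p_cut, fc_cut : float
        thresholds the hit flags were called at.
    """

    table: pd.DataFrame
    bait_label: str
    control_label: str
    p_cut: float = P_CUT
    fc_cut: float = FC_CUT

    @property
    def hits(self) -> set[str]:
        return set(self.table.index[self.table["hit"]])

    @property
    def n_hits(self) -> int:
        return int(self.table["hit"].sum())

    def summary(self) -> str:
        t = self.table
        lines = [
            f"Enrichment contrast: {self.bait_label} vs {self.control_label}",
            f"  proteins tested:   {len(t)}",
            f"  hit rule:          p < {self.p_cut} and log2FC > {self.fc_cut}",
            f"  hits:              {self.n_hits}",
            f"  median log2FC:     {t['log2_fc'].median():.3f}",
            f"  min p-value:       {t['p_value'].min():.3g}",
        ]
        top = t[t["hit"]].sort_values("p_value").head(10)
        if len(top):
            lines.append("  top hits (by p):   " + ", ".join(top.index[:10]))
        return "\n".join(lines)

    def to_tsv(self, path, comments: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in comments or []:
                fh.write(f"# {line}\n")
            out = self.table.copy()
            out.index.name = "protein_id"
            out.to_csv(fh, sep="\t")


class EnrichmentContrast:
    """Model for one bait-vs-control contrast on a log2-stage matrix.

    Parameters
    ----------
    matrix : ProteinGroupMatrix
        at the ``log2`` stage.
    design : pandas.DataFrame
        sample design with ``sample_id`` and ``bait_label`` columns;
        optional ``stimulation`` column to restrict the contrast to one arm.
    bait_label, control_label : str
        values of ``bait_label`` defining the two groups.
    """

    def __init__(self, matrix, design: pd.DataFrame, bait_label: str,
                 control_label: str, stimulation=None):
        if matrix.stage != "log2":
            raise ValueError("EnrichmentContrast requires a log2-stage matrix")
        d = design
        if stimulation is not None and "stimulation" in d.columns:
            d = d[d["stimulation"] == stimulation]
        bait_samples = list(d.loc[d["bait_label"] == bait_label, "sample_id"])
        control_samples = list(d.loc[d["bait_label"] == control_label, "sample_id"])
        if not bait_samples:
            raise ValueError(f"bait label {bait_label!r} not found in design")
        if not control_samples:
            raise ValueError(f"control label {control_label!r} not found in design")
        self.matrix = matrix
        self.bait_label = bait_label
        self.control_label = control_label
        self.bait_samples = bait_samples
        self.control_samples = control_samples

    def fit(self, p_cut: float = P_CUT, fc_cut: float = FC_CUT,
            bh: bool = False) -> EnrichmentResults:
        log2m = self.matrix.intensity
        bait = log2m[self.bait_samples].to_numpy()
        control = log2m[self.control_samples].to_numpy()
        lin_bait = np.exp2(bait)
        lin_control = np.exp2(control)

        n = log2m.shape[0]
        p = np.empty(n)
        fc = np.empty(n)
        ratio = np.empty(n)
        ratio_sd = np.empty(n)
        for i in range(n):
            p[i] = welch_t_test(bait[i], control[i])
            fc[i] = log2_fold_change(bait[i], control[i])
            ratio[i], ratio_sd[i] = propagated_ratio_sd(lin_bait[i], lin_control[i])
        table = pd.DataFrame(
            {"log2_fc": fc, "p_value": p, "mean_ratio": ratio, "ratio_sd": ratio_sd},
            index=log2m.index,
        )
        if bh:
            table["p_adj"] = bh_adjust(p)
        table = call_hits(table, p_cut=p_cut, fc_cut=fc_cut)
        cols = ["log2_fc", "p_value", "hit", "mean_ratio", "ratio_sd"]
        if bh:
            cols.insert(2, "p_adj")
        return EnrichmentResults(
            table=table[cols],
            bait_label=self.bait_label,
            control_label=self.control_label,
            p_cut=p_cut,
            fc_cut=fc_cut,
        )


def enrich_contrast(matrix, design, bait_label, control_label,
                    p_cut: float = P_CUT, fc_cut: float = FC_CUT,
                    stimulation=None) -> EnrichmentResults:
    """Convenience wrapper: build and fit an :class:`EnrichmentContrast`."""
    model = EnrichmentContrast(matrix, design, bait_label, control_label,
                               stimulation=stimulation)
    return model.fit(p_cut=p_cut, fc_cut=fc_cut)


def read_enrichment_table(path) -> pd.DataFrame:
    """Read an enrichment TSV (protein_id, log2_fc, p_value, hit, ...)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if "hit" in df.columns:
        df["hit"] = df["hit"].astype(bool)
    return df
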