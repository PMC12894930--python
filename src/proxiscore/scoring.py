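"""Phosphosite scoring against SH2 specificity matrices.

Each phosphotyrosine site is represented by its ±5-residue window (11
residues, central Y). The raw score is the mean of the enrichment-matrix
values of the ten flanking residues (the central tyrosine is fixed in the
library and carries no information). Scores are normalized so that the
theoretical minimum and maximum achievable raw scores map to 0 and 1 —
a window built from the per-position argmax residues scores exactly 1, the
argmin window exactly 0.

Sites within five residues of a protein terminus have their windows padded
with the gap symbol ``_``; gap positions contribute nothing and shrink the
denominator, the minimal generalization of the ten-residue mean.
With replicate screens, each replicate matrix is normalized with its own
theoretical bounds and the normalized scores are averaged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .display import (
    CENTER_INDEX,
    FLANK_POSITIONS,
    PEPTIDE_LENGTH,
    POSITIONS,
    SpecificityMatrix,
)

GAP = "_"
_FLANK_INDICES = tuple(i for i in range(PEPTIDE_LENGTH) if i != CENTER_INDEX)


def extract_window(sequence: str, site: int) -> str:
    """±5-residue window around a phosphotyrosine (``site`` is 1-based).

    Out-of-range positions are padded with the gap symbol; the residue at
    ``site`` must be Y.
    """
    if not 1 <= site <= len(sequence):
        raise ValueError(f"site {site} outside sequence of length {len(sequence)}")
    if sequence[site - 1] != "Y":
        raise ValueError(f"residue at site {site} is {sequence[site - 1]!r}, not Y")
    chars = []
    for offset in range(-5, 6):
        pos = site - 1 + offset
        chars.append(sequence[pos] if 0 <= pos < len(sequence) else GAP)
    return "".join(chars)


def _values_frame(matrix) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, SpecificityMatrix) else matrix


def raw_score(window: str, matrix) -> tuple[float, int]:
    """Mean enrichment of the flanking residues of one window.

    Returns (score, n_scored). Gap positions are skipped; a full window
    divides by ten. All-gap flanks are an error.
    """
    if len(window) != PEPTIDE_LENGTH:
        raise ValueError(f"window must have length {PEPTIDE_LENGTH}")
    if window[CENTER_INDEX] != "Y":
        raise ValueError("window center must be Y")
    values = _values_frame(matrix)
    total = 0.0
    n_scored = 0
    for i in _FLANK_INDICES:
        residue = window[i]
        if residue == GAP:
            continue
        pos = POSITIONS[i]
        try:
            total += float(values.at[residue, pos])
        except KeyError:
            raise ValueError(f"invalid residue {residue!r} in window {window!r}")
        n_scored += 1
    if n_scored == 0:
        raise ValueError("window has no scorable flanking residues")
    return total / n_scored, n_scored


def theoretical_bounds(matrix) -> tuple[float, float]:
    """Minimum and maximum achievable raw scores for a full window.

    s_max is the mean over the ten flanking positions of each column's
    maximum; s_min analogously with minima (the central column and the gap
    symbol are excluded).
    """
    values = _values_frame(matrix)
    flank = values[list(FLANK_POSITIONS)]
    s_min = float(flank.min(axis=0).mean())
    s_max = float(flank.max(axis=0).mean())
    return s_min, s_max


def normalize_score(raw: float, bounds: tuple[float, float]) -> float:
    """Map a raw score linearly so the theoretical bounds become 0 and 1."""
    s_min, s_max = bounds
    if not s_min < s_max:
        raise ValueError("degenerate bounds: s_min must be < s_max")
    return (raw - s_min) / (s_max - s_min)


def argmax_window(matrix) -> str:
    """The 11-mer taking, at every flanking position, the per-column argmax
    residue (ties broken by residue row order); central Y."""
    values = _values_frame(matrix)
    best = values.idxmax(axis=0)
    chars = [best[p] if p != 0 else "Y" for p in POSITIONS]
    return "".join(chars)


def argmin_window(matrix) -> str:
    """The analogous per-column argmin window; central Y."""
    values = _values_frame(matrix)
    worst = values.idxmin(axis=0)
    chars = [worst[p] if p != 0 else "Y" for p in POSITIONS]
    return "".join(chars)


def score_table(records: pd.DataFrame,
                matrices: dict[str, list[SpecificityMatrix]]) -> pd.DataFrame:
    """Score phosphosite windows against replicate matrices per domain.

    Parameters
    ----------
    records : pandas.DataFrame
        columns ``protein_id``, ``position``, ``window``.
    matrices : dict
        domain label -> list of replicate :class:`SpecificityMatrix`. Each
        replicate is scored and min-max normalized with its own theoretical
        bounds; the normalized scores are then averaged per site.

    Returns a copy of ``records`` with, per domain, a ``<domain>_score``
    column (mean normalized score) and ``<domain>_n_scored`` (number of
    non-gap flanking residues, identical across replicates).
    """
    if not matrices or any(len(reps) == 0 for reps in matrices.values()):
        raise ValueError("need at least one replicate matrix per domain")
    out = records.copy().reset_index(drop=True)
    for domain, reps in matrices.items():
        bounds = [theoretical_bounds(m) for m in reps]
        scores = np.zeros(len(out))
        n_scored_col = np.zeros(len(out), dtype=int)
        for i, window in enumerate(out["window"]):
            per_rep = []
            for m, b in zip(reps, bounds):
                raw, n_scored = raw_score(window, m)
                per_rep.append(normalize_score(raw, b))
            scores[i] = float(np.mean(per_rep))
            n_scored_col[i] = n_scored
        out[f"{domain}_score"] = scores
        out[f"{domain}_n_scored"] = n_scored_col
    return out


def read_phosphosites(path) -> pd.DataFrame:
    """Read a phosphosite TSV (protein_id, position, window)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"protein_id", "position", "window"}
    if not required <= set(df.columns):
        raise ValueError(f"phosphosite table requires columns {sorted(required)}")
    return df
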