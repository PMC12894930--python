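"""Protein-group report preprocessing for label-free proximity-labeling data.

The pipeline mirrors standard TurboID/BioID quantification practice:

1. ``add_lod_noise`` — small additive noise drawn from the lower range of each
   sample's limit of detection (LOD), applied to *all* raw intensities so that
   missing values (stored as 0) become small positive numbers instead of
   being imputed separately.
2. ``filter_low_evidence`` — protein groups averaging fewer than 4.99 MS/MS
   counts across samples are removed.
3. ``normalize_total_intensity`` — each sample is scaled so the total
   intensity of all observable protein groups is identical across samples.
4. ``log2_transform`` — entrywise log2 for downstream fold-change and
   Welch-test analysis.

Stages are enforced by a stage tag so the operations cannot be applied out
of order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STAGES = ("raw", "noised", "filtered", "normalized", "log2")

# which stages each operation accepts as input
_ALLOWED_INPUT = {
    "add_lod_noise": ("raw",),
    "filter_low_evidence": ("raw", "noised"),
    "normalize_total_intensity": ("noised", "filtered"),
    "log2_transform": ("normalized",),
}

MSMS_THRESHOLD = 4.99  # mean MS/MS counts below this are discarded


class StageError(ValueError):
    """An operation was applied to a matrix at the wrong pipeline stage."""


@dataclass
class ProteinGroupMatrix:
    """Protein-group intensities and MS/MS evidence counts across samples.

    Attributes
    ----------
    intensity : pandas.DataFrame
        proteins x samples, non-negative; missing values are encoded as 0.
    msms : pandas.DataFrame or None
        proteins x samples MS/MS counts, aligned to ``intensity``.
    stage : str
        one of ``raw | noised | filtered | normalized | log2``.
    """

    intensity: pd.DataFrame
    msms: pd.DataFrame | None = None
    stage: str = "raw"
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.intensity.index.duplicated().any():
            dups = self.intensity.index[self.intensity.index.duplicated()]
            raise ValueError(f"duplicate protein IDs: {sorted(set(dups))}")
        if self.msms is not None:
            if not self.msms.index.equals(self.intensity.index):
                raise ValueError("msms index does not match intensity index")
            if not self.msms.columns.equals(self.intensity.columns):
                raise ValueError("msms columns do not match intensity columns")
        if self.stage != "log2" and (self.intensity.to_numpy() < 0).any():
            raise ValueError("negative intensities are not allowed")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.intensity.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensity.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def _check_stage(self, op: str) -> None:
        allowed = _ALLOWED_INPUT[op]
        if self.stage not in allowed:
            raise StageError(
                f"{op} requires stage in {allowed}, got {self.stage!r}"
            )

    def to_tsv(self, path, comments: list[str] | None = None) -> None:
        """Write intensities (and MS/MS columns as ``<sample>.msms``) to TSV."""
        df = self.intensity.copy()
        if self.msms is not None:
            for s in self.sample_ids:
                df[f"{s}.msms"] = self.msms[s]
        df.index.name = "protein_id"
        with open(path, "w") as fh:
            for line in comments or []:
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t")


def read_protein_groups(report, design: pd.DataFrame,
                        stage: str = "raw") -> ProteinGroupMatrix:
    """Read a protein-group report TSV aligned to a sample design table.

    Parameters
    ----------
    report : path
        TSV with protein IDs in the first column, one intensity column per
        design sample and optional ``<sample_id>.msms`` columns. Missing
        cells are read as 0.
    design : pandas.DataFrame
        sample design with a ``sample_id`` column; the matrix columns are
        ordered to match it.
    """
    df = pd.read_csv(report, sep="\t", comment="#", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()]
        raise ValueError(f"duplicate protein IDs in report: {sorted(set(dups))}")
    samples = list(design["sample_id"])
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample_ids in design")
    missing = [s for s in samples if s not in df.columns]
    if missing:
        raise ValueError(f"design samples absent from report: {missing}")
    intensity = df[samples].fillna(0.0).astype(float)
    msms_cols = [f"{s}.msms" for s in samples]
    msms = None
    if all(c in df.columns for c in msms_cols):
        msms = df[msms_cols].fillna(0.0).astype(float)
        msms.columns = samples
    return ProteinGroupMatrix(intensity=intensity, msms=msms, stage=stage)


def read_design(path) -> pd.DataFrame:
    """Read a sample design TSV (sample_id, bait_label, stimulation, ...)."""
    design = pd.read_csv(path, sep="\t", comment="#")
    if "sample_id" not in design.columns or "bait_label" not in design.columns:
        raise ValueError("design table requires sample_id and bait_label columns")
    if design["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_ids in design")
    return design


def add_lod_noise(
    matrix: ProteinGroupMatrix,
    seed: int,
    lod_percentile: float = 1.0,
    lower_fraction: float = 0.1,
) -> ProteinGroupMatrix:
    """Add sub-LOD noise to every raw intensity (missing values included).

    Per sample ``s`` the limit of detection ``LOD_s`` is the
    ``lod_percentile``-th percentile of that sample's nonzero raw
    intensities; every entry receives an independent additive draw from
    ``Uniform(lower_fraction * LOD_s, LOD_s)``. Zeros (missing values)
    therefore become small positive numbers, and all entries are > 0
    afterwards.
    """
    matrix._check_stage("add_lod_noise")
    rng = np.random.default_rng(seed)
    values = matrix.intensity.to_numpy(dtype=float, copy=True)
    for j, sample in enumerate(matrix.sample_ids):
        col = values[:, j]
        nonzero = col[col > 0]
        if nonzero.size == 0:
            raise ValueError(f"sample {sample!r} has no nonzero intensities")
        lod = float(np.percentile(nonzero, lod_percentile))
        col += rng.uniform(lower_fraction * lod, lod, size=col.shape)
    out = pd.DataFrame(values, index=matrix.intensity.index, columns=matrix.intensity.columns)
    return replace(
        matrix,
        intensity=out,
        stage="noised",
        log=matrix.log + [f"add_lod_noise: seed={seed}"],
    )


def filter_low_evidence(
    matrix: ProteinGroupMatrix, threshold: float = MSMS_THRESHOLD
) -> ProteinGroupMatrix:
    """Drop protein groups whose mean MS/MS count across samples is < threshold.

    The comparison is strict: a protein with mean count exactly equal to the
    threshold is retained. The mean is taken across all samples jointly.
    """
    matrix._check_stage("filter_low_evidence")
    if matrix.msms is None:
        raise ValueError("filter_low_evidence requires MS/MS counts")
    mean_msms = matrix.msms.mean(axis=1)
    keep = mean_msms >= threshold
    n_removed = int((~keep).sum())
    return replace(
        matrix,
        intensity=matrix.intensity.loc[keep],
        msms=matrix.msms.loc[keep],
        stage="filtered",
        log=matrix.log
        + [f"filter_low_evidence: threshold={threshold}, removed={n_removed}"],
    )


def normalize_total_intensity(matrix: ProteinGroupMatrix) -> ProteinGroupMatrix:
    """Equalize total intensity across samples.

    Each column is divided by its own sum and rescaled by the mean of all
    column sums, so every column sum equals the grand mean total and
    magnitudes stay on the original scale.
    """
    matrix._check_stage("normalize_total_intensity")
    totals = matrix.intensity.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero total intensity in samples: {bad}")
    target = float(totals.mean())
    out = matrix.intensity / totals * target
    return replace(
        matrix,
        intensity=out,
        stage="normalized",
        log=matrix.log + [f"normalize_total_intensity: target={target:.6g}"],
    )


def log2_transform(matrix: ProteinGroupMatrix) -> ProteinGroupMatrix:
    """Entrywise log2; requires strictly positive entries (noise stage)."""
    matrix._check_stage("log2_transform")
    values = matrix.intensity.to_numpy()
    if (values <= 0).any():
        raise ValueError("log2_transform requires all intensities > 0")
    out = pd.DataFrame(
        np.log2(values), index=matrix.intensity.index, columns=matrix.intensity.columns
    )
    return replace(matrix, intensity=out, stage="log2", log=matrix.log + ["log2_transform"])


def preprocess_pipeline(
    matrix: ProteinGroupMatrix,
    seed: int,
    msms_threshold: float = MSMS_THRESHOLD,
    lod_percentile: float = 1.0,
    lower_fraction: float = 0.1,
) -> ProteinGroupMatrix:
    """Run the full preprocessing chain: noise -> filter -> normalize -> log2."""
    m = add_lod_noise(matrix, seed=seed, lod_percentile=lod_percentile,
                      lower_fraction=lower_fraction)
    if m.msms is not None:
        m = filter_low_evidence(m, threshold=msms_threshold)
    m = normalize_total_intensity(m)
    return log2_transform(m)
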