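"""Synthetic data with known ground truth for the whole analysis pipeline.

Three generators emulate the statistical structure of the real experiments:

* :func:`simulate_interactome_experiment` — a bait-vs-control proximity-
  labeling experiment. Per-protein log2 intensities are Normal(baseline +
  bait-specific effect, replicate_sd) and exponentiated, giving log-normal
  protein-group intensities; true interactors carry a multiplicative
  enrichment ``2**delta`` in bait samples only. Intensities below a
  detection limit drop out (are stored as 0, the report convention for
  missing values) with a fixed probability, and MS/MS counts are Poisson
  with mean proportional to intensity.
* :func:`simulate_display_screen` — an X5-Y-X5 peptide-display selection.
  Input reads are uniform random 11-mers with fixed central Y; selected
  reads are resampled (with replacement, mimicking PCR/sequencing
  resampling) with probability proportional to ``exp(beta * s_true)`` where
  ``s_true`` sums a ground-truth energy matrix over the flanking positions.
* :func:`simulate_phosphoproteome` — a phosphosite catalogue in which a
  declared subset of windows is planted to score highly under the true
  energy matrix, on a graded quality tier.

Every generator is a pure function of (truth, config, seed).
:func:`evaluate_recovery` closes the loop: sensitivity and observed FDR of
hit calls against the spike-in set, and the Pearson correlation between a
recovered specificity matrix and the true energy matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .display import AMINO_ACIDS, FLANK_POSITIONS, PEPTIDE_LENGTH, POSITIONS, PeptideSet
from .interactome import COMPARTMENTS
from .preprocess import ProteinGroupMatrix

_AA_ARRAY = np.array(list(AMINO_ACIDS), dtype="<U1")
_FLANK_COL_IDX = [POSITIONS.index(p) for p in FLANK_POSITIONS]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study conditions.

    Defaults reflect a typical TurboID experiment: ~2000 quantified protein
    groups spanning a wide (log-normal) dynamic range, 50 true interactors
    at a 4-fold (2 log2 units) enrichment, 3 biological replicates per
    condition, and replicate noise of 0.5 log2 units.
    """

    n_proteins: int = 2000
    n_interactors: int = 50
    interactor_effect: float = 2.0   # delta, log2 units
    n_replicates: int = 3
    replicate_sd: float = 0.5        # log2 units
    baseline_mean: float = 20.0      # log2 intensity units
    baseline_sd: float = 2.0
    detection_limit: float = 1e5     # intensity units
    dropout_below_lod: float = 0.5   # probability
    msms_rate_per_intensity: float = 20.0  # mean MS/MS at median intensity
    n_reads_input: int = 100_000
    n_reads_selected: int = 100_000
    selection_sharpness: float = 0.5  # beta; keeps log2(freq ratio) quasi-linear in energy
    n_sites: int = 400
    planted_fraction: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_proteins": self.n_proteins,
            "n_interactors": self.n_interactors,
            "n_replicates": self.n_replicates,
            "n_reads_input": self.n_reads_input,
            "n_reads_selected": self.n_reads_selected,
            "n_sites": self.n_sites,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.n_interactors > self.n_proteins:
            raise ValueError("n_interactors cannot exceed n_proteins")
        for name in ("dropout_below_lod", "planted_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be >= 0")
        if self.detection_limit < 0 or self.msms_rate_per_intensity < 0:
            raise ValueError("detection_limit and msms rate must be >= 0")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in asdict(self).items():
                fh.write(f"{key}\t{value}\n")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        kwargs = {}
        fields = cls.__dataclass_fields__
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("\t")
                if key not in fields:
                    raise ValueError(f"unknown config key {key!r}")
                kwargs[key] = type(fields[key].default)(value)
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """The simulated world: what downstream analyses should recover."""

    protein_ids: list[str]
    baseline_log2_abundance: np.ndarray
    interactor_effect: np.ndarray  # delta per protein, 0 for non-interactors
    annotation: pd.DataFrame
    energy_matrix: pd.DataFrame    # 20 residues x 11 positions, center column 0
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.protein_ids)
        if len(self.baseline_log2_abundance) != n or len(self.interactor_effect) != n:
            raise ValueError("per-protein arrays must match protein_ids length")
        if self.energy_matrix.shape != (20, PEPTIDE_LENGTH):
            raise ValueError("energy matrix must be 20 residues x 11 positions")

    @property
    def spike_ins(self) -> set[str]:
        ids = np.asarray(self.protein_ids)
        return set(ids[self.interactor_effect > 0])

    def to_tsv(self, path) -> None:
        df = self.annotation.copy()
        df.insert(0, "baseline_log2_abundance", self.baseline_log2_abundance)
        df.insert(1, "interactor_effect", self.interactor_effect)
        df.index.name = "protein_id"
        df.to_csv(path, sep="\t")


def make_energy_matrix(rng: np.random.Generator, n_effect_cells: int = 6,
                       effect: float = 2.0) -> pd.DataFrame:
    """Sparse ground-truth energy matrix: +/-effect on a few flanking cells.

    Half the chosen cells get +effect (preferred residues), half -effect
    (disfavored); all other cells, and the whole central column, are 0.
    A hard, exactly identifiable target for matrix-recovery benchmarks.
    """
    values = np.zeros((20, PEPTIDE_LENGTH))
    flank_cols = np.asarray(_FLANK_COL_IDX)
    cells = rng.choice(20 * len(flank_cols), size=n_effect_cells, replace=False)
    for k, cell in enumerate(cells):
        row, col = divmod(cell, len(flank_cols))
        values[row, flank_cols[col]] = effect if k < (n_effect_cells + 1) // 2 else -effect
    return pd.DataFrame(values, index=list(AMINO_ACIDS), columns=list(POSITIONS))


def make_dense_energy_matrix(rng: np.random.Generator,
                             scale: float = 0.75) -> pd.DataFrame:
    """Dense ground-truth energy matrix: Normal(0, scale) on flanking cells.

    Mirrors real SH2 specificity profiles, where every residue carries some
    preference or aversion at every position; the central (fixed Y) column
    is 0.
    """
    values = np.zeros((20, PEPTIDE_LENGTH))
    values[:, _FLANK_COL_IDX] = rng.normal(0.0, scale, size=(20, 10))
    return pd.DataFrame(values, index=list(AMINO_ACIDS), columns=list(POSITIONS))


def make_ground_truth(config: SimulationConfig, seed: int | None = None,
                      energy: str = "dense") -> GroundTruth:
    """Draw a ground truth consistent with ``config``.

    Annotation realism: true interactors are enriched for phosphoprotein
    flags (the bait binds phosphoproteins) and contribute most of the
    reference-interactor list; a sprinkling of reference interactors among
    non-interactors emulates literature interactions not captured by the
    experiment.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = config.n_proteins
    protein_ids = [f"P{i:05d}" for i in range(n)]
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    delta = np.zeros(n)
    interactors = rng.choice(n, size=config.n_interactors, replace=False)
    delta[interactors] = config.interactor_effect

    is_interactor = delta > 0
    p_phos = np.where(is_interactor, 0.8, 0.3)
    is_phospho = rng.random(n) < p_phos
    is_mito = rng.random(n) < 0.15
    compartment = np.where(
        is_mito, rng.choice(COMPARTMENTS[:4], size=n), "unknown"
    )
    is_reference = (is_interactor & (rng.random(n) < 0.6)) | (
        ~is_interactor & (rng.random(n) < 0.02)
    )
    annotation = pd.DataFrame(
        {
            "is_phosphoprotein": is_phospho,
            "is_mitochondrial": is_mito,
            "compartment": compartment,
            "is_reference_interactor": is_reference,
        },
        index=pd.Index(protein_ids, name="protein_id"),
    )
    if energy == "dense":
        energy = make_dense_energy_matrix(rng)
    elif energy == "sparse":
        energy = make_energy_matrix(rng)
    else:
        raise ValueError("energy must be 'dense' or 'sparse'")
    return GroundTruth(
        protein_ids=protein_ids,
        baseline_log2_abundance=baseline,
        interactor_effect=delta,
        annotation=annotation,
        energy_matrix=energy,
        seed=seed,
    )


def _check_sizes(truth: GroundTruth, config: SimulationConfig) -> None:
    if len(truth.protein_ids) != config.n_proteins:
        raise ValueError(
            f"truth has {len(truth.protein_ids)} proteins but config expects "
            f"{config.n_proteins}"
        )
    if int((truth.interactor_effect > 0).sum()) > config.n_proteins:
        raise ValueError("more interactors than proteins")


def simulate_interactome_experiment(
    truth: GroundTruth,
    config: SimulationConfig,
    seed: int | None = None,
    bait_label: str = "WT",
    control_label: str = "TurboID",
    stimulation: bool = False,
) -> tuple[ProteinGroupMatrix, pd.DataFrame]:
    """Simulate one bait-vs-control TurboID experiment.

    Returns a raw-stage :class:`ProteinGroupMatrix` (bait then control
    replicates) and the matching sample design table. Noise draws are made
    before the interactor effect is added, so with a fixed seed increasing
    one protein's effect can only increase its realized bait intensities.
    """
    config.validate()
    _check_sizes(truth, config)
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = config.n_proteins
    reps = config.n_replicates
    n_samples = 2 * reps
    bait_mask = np.zeros(n_samples, dtype=bool)
    bait_mask[:reps] = True

    noise = rng.normal(0.0, config.replicate_sd, size=(n, n_samples))
    dropout_u = rng.random((n, n_samples))
    log2_int = (
        truth.baseline_log2_abundance[:, None]
        + truth.interactor_effect[:, None] * bait_mask[None, :]
        + noise
    )
    intensity = np.exp2(log2_int)
    dropped = (intensity < config.detection_limit) & (
        dropout_u < config.dropout_below_lod
    )
    intensity[dropped] = 0.0

    median_int = np.median(np.exp2(truth.baseline_log2_abundance))
    msms_mean = config.msms_rate_per_intensity * intensity / median_int
    msms = rng.poisson(msms_mean).astype(float)

    sample_ids = [f"{bait_label}_{'EGF_' if stimulation else ''}r{r + 1}" for r in range(reps)]
    sample_ids += [f"{control_label}_{'EGF_' if stimulation else ''}r{r + 1}" for r in range(reps)]
    design = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "bait_label": [bait_label] * reps + [control_label] * reps,
            "stimulation": stimulation,
            "biotin": True,
            "inhibitor": False,
            "replicate": list(range(1, reps + 1)) * 2,
        }
    )
    idx = pd.Index(truth.protein_ids, name="protein_id")
    matrix = ProteinGroupMatrix(
        intensity=pd.DataFrame(intensity, index=idx, columns=sample_ids),
        msms=pd.DataFrame(msms, index=idx, columns=sample_ids),
        stage="raw",
    )
    return matrix, design


def _ints_to_peptides(flank_idx: np.ndarray) -> list[str]:
    """(n, 10) residue indices -> list of 11-mer strings with central Y."""
    n = flank_idx.shape[0]
    chars = np.empty((n, PEPTIDE_LENGTH), dtype="<U1")
    chars[:, :5] = _AA_ARRAY[flank_idx[:, :5]]
    chars[:, 5] = "Y"
    chars[:, 6:] = _AA_ARRAY[flank_idx[:, 5:]]
    return np.ascontiguousarray(chars).view(f"<U{PEPTIDE_LENGTH}").ravel().tolist()


def simulate_display_screen(
    truth: GroundTruth, config: SimulationConfig, seed: int | None = None,
    replicate: int = 1,
) -> tuple[PeptideSet, PeptideSet]:
    """Simulate an X5-Y-X5 display selection against the true energy matrix.

    Input reads are uniform over the 20 residues at each flanking position;
    selected reads are drawn with replacement from the input pool with
    probability proportional to ``exp(beta * s_true)``, ``s_true`` being the
    sum of energy-matrix entries over the ten flanking positions.
    """
    config.validate()
    if truth.energy_matrix is None:
        raise ValueError("ground truth has no energy matrix")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n_in = config.n_reads_input
    flank_idx = rng.integers(0, 20, size=(n_in, 10))
    energy = truth.energy_matrix.to_numpy()[:, _FLANK_COL_IDX]  # 20 x 10
    s_true = energy[flank_idx, np.arange(10)[None, :]].sum(axis=1)
    weights = np.exp(config.selection_sharpness * s_true)
    probs = weights / weights.sum()
    chosen = rng.choice(n_in, size=config.n_reads_selected, replace=True, p=probs)

    input_set = PeptideSet(_ints_to_peptides(flank_idx), source="input",
                           replicate=replicate)
    selected_set = PeptideSet(_ints_to_peptides(flank_idx[chosen]),
                              source="selected", replicate=replicate)
    return input_set, selected_set


def simulate_phosphoproteome(
    truth: GroundTruth, n_sites: int, seed: int | None = None,
    planted_fraction: float = 0.25,
) -> pd.DataFrame:
    """Simulate a phosphosite catalogue with planted high-scoring windows.

    A fraction of sites is "planted" on a graded quality tier t in (0, 1]:
    round(10 t) of the ten flanking positions (chosen at random) carry the
    per-column argmax residue of the true energy matrix, the rest are
    uniform random; the planted-position count is deterministic in t so the
    tier is a faithful ordinal of window quality. Unplanted sites (tier 0)
    are uniform random. Returns a table with protein_id, position, window,
    tier and planted columns.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n_planted = int(round(planted_fraction * n_sites))
    tiers = np.zeros(n_sites)
    if n_planted:
        tiers[:n_planted] = np.linspace(0.1, 1.0, n_planted)

    energy = truth.energy_matrix.to_numpy()[:, _FLANK_COL_IDX]
    argmax_rows = energy.argmax(axis=0)  # per flanking column
    flank_idx = rng.integers(0, 20, size=(n_sites, 10))
    n_argmax = np.rint(10 * tiers).astype(int)
    rank = rng.random((n_sites, 10)).argsort(axis=1)  # random position order
    use_argmax = rank < n_argmax[:, None]
    flank_idx = np.where(use_argmax, argmax_rows[None, :], flank_idx)

    windows = _ints_to_peptides(flank_idx)
    proteins = rng.choice(truth.protein_ids, size=n_sites, replace=True)
    positions = rng.integers(6, 500, size=n_sites)
    return pd.DataFrame(
        {
            "protein_id": proteins,
            "position": positions,
            "window": windows,
            "tier": tiers,
            "planted": tiers > 0,
        }
    )


@dataclass
class RecoveryReport:
    """How well the pipeline recovered the simulated ground truth."""

    sensitivity: float
    fdr: float
    matrix_r: float = float("nan")
    n_true: int = 0
    n_called: int = 0

    def summary(self) -> str:
        lines = [
            "Ground-truth recovery",
            f"  spike-ins:    {self.n_true}",
            f"  called hits:  {self.n_called}",
            f"  sensitivity:  {self.sensitivity:.3f}",
            f"  observed FDR: {self.fdr:.3f}",
        ]
        if np.isfinite(self.matrix_r):
            lines.append(f"  matrix Pearson r: {self.matrix_r:.3f}")
        return "\n".join(lines)


def evaluate_recovery(called_hits, truth: GroundTruth,
                      recovered_matrix=None) -> RecoveryReport:
    """Sensitivity/FDR of hit calls and correlation of a recovered matrix.

    sensitivity = TP / (TP + FN) over the spike-in set;
    FDR = FP / max(1, FP + TP);
    matrix_r = Pearson r between the flanking entries of the recovered
    specificity matrix and the true energy matrix, flattened.
    """
    calls = set(called_hits)
    spike = truth.spike_ins
    tp = len(calls & spike)
    fp = len(calls - spike)
    sensitivity = tp / len(spike) if spike else 0.0
    fdr = fp / max(1, fp + tp)
    matrix_r = float("nan")
    if recovered_matrix is not None:
        if isinstance(recovered_matrix, pd.DataFrame):
            rec = recovered_matrix
        else:  # SpecificityMatrix
            rec = recovered_matrix.values
        rec_flank = rec[list(FLANK_POSITIONS)].to_numpy().ravel()
        true_flank = truth.energy_matrix[list(FLANK_POSITIONS)].to_numpy().ravel()
        matrix_r = float(np.corrcoef(rec_flank, true_flank)[0, 1])
    return RecoveryReport(
        sensitivity=float(sensitivity),
        fdr=float(fdr),
        matrix_r=matrix_r,
        n_true=len(spike),
        n_called=len(calls),
    )
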