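"""Position-specific enrichment matrices from X5-Y-X5 peptide-display screens.

A degenerate 11-mer library (five random residues on either side of a fixed
central tyrosine) is displayed, phosphorylated and selected for SH2 binding;
deep sequencing of the input and selected pools yields per-position residue
counts. The specificity profile is the log2 ratio of selected to input
per-position residue frequencies — a position-specific weight matrix (PSWM)
with 11 position columns (-5 ... +5) and 20 residue rows.

A pseudocount added to every cell of both counts matrices before the
frequency conversion keeps the log-ratio finite when a residue is absent
from one pool at some position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

# residue row order, grouped by biochemical property:
# small, aliphatic/hydrophobic, aromatic, basic, acidic/amide
AMINO_ACIDS = "GASTCPVILMFWYHKRDENQ"
POSITIONS = tuple(range(-5, 6))  # 11 positions, central Y at 0
PEPTIDE_LENGTH = 11
CENTER_INDEX = 5
FLANK_POSITIONS = tuple(p for p in POSITIONS if p != 0)

_AA_SET = frozenset(AMINO_ACIDS)
_NT_SET = frozenset("ACGTN")


@dataclass
class PeptideSet:
    """A pool of 11-mer peptides with fixed central tyrosine."""

    peptides: list[str]
    source: str = "input"  # "input" | "selected"
    replicate: int = 1

    def __len__(self) -> int:
        return len(self.peptides)


@dataclass
class RejectionLog:
    """Per-reason tally of reads rejected during peptide loading."""

    wrong_length: int = 0
    stop_codon: int = 0
    non_y_center: int = 0
    invalid_character: int = 0
    retained: int = 0

    @property
    def total(self) -> int:
        return (self.wrong_length + self.stop_codon + self.non_y_center
                + self.invalid_character + self.retained)


@dataclass
class CountsMatrix:
    """Per-position residue counts: 20 residue rows x 11 position columns."""

    counts: pd.DataFrame
    n_peptides: int

    def __post_init__(self) -> None:
        if self.counts.shape != (20, PEPTIDE_LENGTH):
            raise ValueError(f"counts matrix must be 20x11, got {self.counts.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class SpecificityMatrix:
    """Log2 enrichment (selected vs input) PSWM for one SH2 screen.

    ``values`` is a 20 residue x 11 position DataFrame; the central column
    (position 0) corresponds to the fixed tyrosine and is excluded from
    phosphosite scoring.
    """

    values: pd.DataFrame
    pseudocount: float = 1.0
    domain: str = ""
    replicates: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.shape != (20, PEPTIDE_LENGTH):
            raise ValueError(f"matrix must be 20x11, got {self.values.shape}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("enrichment matrix must be finite everywhere")

    @property
    def flanking(self) -> pd.DataFrame:
        """The 20x10 sub-matrix over the flanking (non-center) positions."""
        return self.values[list(FLANK_POSITIONS)]

    def summary(self) -> str:
        flat = self.flanking.to_numpy()
        imax = np.unravel_index(flat.argmax(), flat.shape)
        imin = np.unravel_index(flat.argmin(), flat.shape)
        return "\n".join([
            f"Specificity matrix{' for ' + self.domain if self.domain else ''}",
            f"  replicates averaged: {self.replicates or [1]}",
            f"  pseudocount:         {self.pseudocount}",
            f"  strongest preference: {AMINO_ACIDS[imax[0]]} at "
            f"{FLANK_POSITIONS[imax[1]]:+d} (log2 {flat[imax]:.2f})",
            f"  strongest aversion:   {AMINO_ACIDS[imin[0]]} at "
            f"{FLANK_POSITIONS[imin[1]]:+d} (log2 {flat[imin]:.2f})",
        ])

    def to_tsv(self, path, comments: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in comments or []:
                fh.write(f"# {line}\n")
            out = self.values.copy()
            out.index.name = "residue"
            out.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path, domain: str = "") -> "SpecificityMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        df.columns = [int(c) for c in df.columns]
        df = df.reindex(index=list(AMINO_ACIDS), columns=list(POSITIONS))
        if df.isna().any().any():
            raise ValueError("matrix TSV missing residues or positions")
        return cls(values=df, domain=domain)


def _classify_read(read: str, expected_length: int) -> str:
    chars = set(read.upper())
    if len(read) == 3 * expected_length and chars <= _NT_SET:
        return "nt"
    return "aa"


def load_peptides(reads, expected_length: int = PEPTIDE_LENGTH,
                  require_center_y: bool = True, source: str = "input",
                  replicate: int = 1) -> tuple[PeptideSet, RejectionLog]:
    """Filter (and if nucleotide, translate) reads into a valid PeptideSet.

    ``reads`` is an iterable of strings: amino-acid peptides of the expected
    length, or nucleotide sequences of exactly 3x that length (translated
    with the standard genetic code). Mixing the two in one input is an
    error. Reads are rejected — and tallied by reason — when they have the
    wrong length, contain a stop codon, have a non-Y center (library design
    fixes the central tyrosine) or contain an invalid character.
    """
    log = RejectionLog()
    peptides: list[str] = []
    mode: str | None = None
    for read in reads:
        read = str(read).strip().upper()
        if not read:
            continue
        kind = _classify_read(read, expected_length)
        if mode is None:
            mode = kind
        elif kind != mode:
            raise ValueError("mixed nucleotide and amino-acid reads in one input")
        if mode == "nt":
            if len(read) != 3 * expected_length:
                log.wrong_length += 1
                continue
            if "N" in read:
                log.invalid_character += 1
                continue
            pep = str(Seq(read).translate())
        else:
            pep = read
        if len(pep) != expected_length:
            log.wrong_length += 1
            continue
        if "*" in pep:
            log.stop_codon += 1
            continue
        if not set(pep) <= _AA_SET:
            log.invalid_character += 1
            continue
        if require_center_y and pep[CENTER_INDEX] != "Y":
            log.non_y_center += 1
            continue
        peptides.append(pep)
        log.retained += 1
    return PeptideSet(peptides, source=source, replicate=replicate), log


def read_peptide_file(path) -> list[str]:
    """Read peptides/reads from FASTQ (by extension) or one-per-line text."""
    path = str(path)
    if path.endswith((".fastq", ".fq")):
        from Bio import SeqIO

        return [str(rec.seq) for rec in SeqIO.parse(path, "fastq")]
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def build_counts_matrix(peptides: PeptideSet) -> CountsMatrix:
    """Count residue occurrences at every position: 20x11 counts matrix."""
    if len(peptides) == 0:
        raise ValueError("cannot count an empty peptide set")
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    arr = np.frombuffer("".join(peptides.peptides).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(peptides), PEPTIDE_LENGTH)
    lut = np.full(128, -1, dtype=np.int64)
    for aa, i in aa_index.items():
        lut[ord(aa)] = i
    idx = lut[arr]
    counts = np.zeros((20, PEPTIDE_LENGTH), dtype=np.int64)
    for j in range(PEPTIDE_LENGTH):
        counts[:, j] = np.bincount(idx[:, j], minlength=20)
    df = pd.DataFrame(counts, index=list(AMINO_ACIDS), columns=list(POSITIONS))
    return CountsMatrix(counts=df, n_peptides=len(peptides))


def to_frequencies(counts: CountsMatrix, pseudocount: float = 0.0) -> pd.DataFrame:
    """Per-position residue frequencies; every column sums to 1.

    With a pseudocount c, each cell becomes (count + c) / (n + 20c).
    """
    if counts.n_peptides <= 0:
        raise ValueError("n_peptides must be > 0")
    adj = counts.counts.astype(float) + pseudocount
    return adj / adj.sum(axis=0)


def enrichment_matrix(selected: CountsMatrix, input_: CountsMatrix,
                      pseudocount: float = 1.0, domain: str = "",
                      replicate: int = 1) -> SpecificityMatrix:
    """log2(selected frequency / input frequency), pseudocount-stabilized."""
    if selected.shape != input_.shape:
        raise ValueError("counts matrices have mismatched shapes")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0 to guarantee finite values")
    f_sel = to_frequencies(selected, pseudocount)
    f_in = to_frequencies(input_, pseudocount)
    values = np.log2(f_sel / f_in)
    return SpecificityMatrix(values=values, pseudocount=pseudocount,
                             domain=domain, replicates=[replicate])


def average_matrices(matrices: list[SpecificityMatrix]) -> SpecificityMatrix:
    """Entrywise mean of replicate screens; domain labels must agree."""
    if not matrices:
        raise ValueError("need at least one matrix")
    domains = {m.domain for m in matrices}
    if len(domains) > 1:
        raise ValueError(f"cannot average across domains: {sorted(domains)}")
    stacked = np.mean([m.values.to_numpy() for m in matrices], axis=0)
    values = pd.DataFrame(stacked, index=matrices[0].values.index,
                          columns=matrices[0].values.columns)
    reps = sorted({r for m in matrices for r in m.replicates})
    return SpecificityMatrix(values=values, pseudocount=matrices[0].pseudocount,
                             domain=matrices[0].domain, replicates=reps)


class DisplayScreen:
    """Model for one SH2 display screen: input and selected peptide pools.

    ``fit()`` filters nothing (pools are assumed pre-filtered by
    :func:`load_peptides`), counts both pools, and returns the
    pseudocount-stabilized log2 enrichment :class:`SpecificityMatrix`.
    """

    def __init__(self, input_peptides: PeptideSet, selected_peptides: PeptideSet,
                 domain: str = "", pseudocount: float = 1.0):
        self.input_peptides = input_peptides
        self.selected_peptides = selected_peptides
        self.domain = domain
        self.pseudocount = pseudocount

    def fit(self) -> SpecificityMatrix:
        c_in = build_counts_matrix(self.input_peptides)
        c_sel = build_counts_matrix(self.selected_peptides)
        return enrichment_matrix(
            c_sel, c_in, pseudocount=self.pseudocount, domain=self.domain,
            replicate=self.selected_peptides.replicate,
        )
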