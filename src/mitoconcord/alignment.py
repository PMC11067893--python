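"""Alignment I/O and sequence-side informativeness metrics.

Covers the per-partition alignment statistics used to characterise marker
quality: alignment length, parsimony-informative (PI) site counts, the
standardized information content (SIC = PI sites per kilobase), and pairwise
uncorrected / model-corrected distance matrices for saturation analysis.

Conventions (declared, since toolchains differ): gaps and IUPAC ambiguity
codes are treated as missing data — they are never counted as character
states for PI sites and are deleted pairwise when computing distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "read_fasta_alignment",
    "read_partition_file",
    "count_parsimony_informative",
    "sic",
    "sic_from_counts",
    "p_distance_matrix",
    "corrected_distance_matrix",
]

_BASES = "ACGT"
# IUPAC codes -> compatible unambiguous bases (used by the likelihood module too)
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT",
}


@dataclass
class Alignment:
    """An ordered multiple sequence alignment over IUPAC DNA plus gaps.

    ``partition_map`` maps partition names to 1-based inclusive column ranges.
    """

    taxa: list
    sequences: list
    partition_map: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa and sequences differ in number")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxon labels: {dupes}")
        if not self.sequences:
            raise ValueError("empty alignment")
        norm = []
        length = len(self.sequences[0])
        for taxon, seq in zip(self.taxa, self.sequences):
            seq = seq.upper().replace("U", "T")
            if len(seq) != length:
                raise ValueError(
                    f"record {taxon!r} has length {len(seq)}, expected {length}"
                )
            bad = set(seq) - set(IUPAC)
            if bad:
                raise ValueError(f"record {taxon!r} contains invalid symbols {sorted(bad)}")
            norm.append(seq)
        self.sequences = norm
        for name, (start, end) in self.partition_map.items():
            if not (1 <= start <= end <= length):
                raise ValueError(
                    f"partition {name!r} range ({start}, {end}) outside [1, {length}]"
                )
        self._matrix: Optional[np.ndarray] = None

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def matrix(self) -> np.ndarray:
        """Character matrix as an (n_taxa, length) array of single-byte strings."""
        if self._matrix is None:
            self._matrix = np.array(
                [np.frombuffer(s.encode(), dtype="S1") for s in self.sequences]
            )
        return self._matrix

    def base_codes(self) -> np.ndarray:
        """A/C/G/T -> 0..3; gaps and ambiguity codes -> 255."""
        codes = np.full(self.matrix().shape, 255, dtype=np.uint8)
        for i, b in enumerate(_BASES):
            codes[self.matrix() == b.encode()] = i
        return codes

    def columns(self, column_range: Optional[Tuple[int, int]] = None) -> slice:
        """Convert a 1-based inclusive range to a column slice (whole alignment if None)."""
        if column_range is None:
            return slice(0, self.length)
        start, end = column_range
        if not (1 <= start <= end <= self.length):
            raise ValueError(f"column range ({start}, {end}) outside [1, {self.length}]")
        return slice(start - 1, end)

    def extract(self, column_range: Tuple[int, int], partitions: Optional[dict] = None) -> "Alignment":
        """New alignment restricted to a 1-based inclusive column range."""
        sl = self.columns(column_range)
        return Alignment(
            taxa=list(self.taxa),
            sequences=[s[sl] for s in self.sequences],
            partition_map=dict(partitions or {}),
        )

    def partition(self, name: str) -> "Alignment":
        if name not in self.partition_map:
            raise KeyError(f"no partition named {name!r}")
        return self.extract(self.partition_map[name])

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for taxon, seq in zip(self.taxa, self.sequences):
                fh.write(f">{taxon}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


@dataclass
class DistanceMatrix:
    """A symmetric pairwise distance matrix with a fixed label order.

    Undefined entries (no comparable sites, or saturated beyond the model
    bound) are NaN, never silently zero.
    """

    labels: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")

    @property
    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(len(self.labels), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major pair order (may contain NaN)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.values):
                cells = " ".join("NA" if np.isnan(v) else f"{v:.6f}" for v in row)
                fh.write(f"{label}  {cells}\n")


def read_fasta_alignment(path, partition_map: Optional[dict] = None) -> Alignment:
    """Read an aligned FASTA file; records must all have the same length."""
    taxa, seqs = [], []
    for record in SeqIO.parse(str(path), "fasta"):
        taxa.append(record.id)
        seqs.append(str(record.seq))
    if not taxa:
        raise ValueError(f"no FASTA records found in {path}")
    return Alignment(taxa=taxa, sequences=seqs, partition_map=dict(partition_map or {}))


def read_partition_file(path) -> Dict[str, Tuple[int, int]]:
    """Read a partition table: RAxML-style ('DNA, ND2 = 1-1059') or CSV (gene,start,end)."""
    partitions: Dict[str, Tuple[int, int]] = {}
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" in line:  # RAxML style
            left, right = line.split("=", 1)
            name = left.split(",")[-1].strip()
            start_s, end_s = right.strip().split("-")
        else:
            fields = [f.strip() for f in line.split(",")]
            if fields[0].lower() in ("gene", "partition", "name"):
                continue
            name, start_s, end_s = fields[:3]
        if name in partitions:
            raise ValueError(f"duplicate partition name {name!r} (line {lineno})")
        partitions[name] = (int(start_s), int(end_s))
    if not partitions:
        raise ValueError(f"no partitions found in {path}")
    return partitions


def count_parsimony_informative(
    aln: Alignment, column_range: Optional[Tuple[int, int]] = None
) -> int:
    """Number of parsimony-informative columns.

    A column is informative when at least two distinct unambiguous nucleotide
    states each occur in at least two sequences; gaps and ambiguity codes are
    missing data, never states.
    """
    codes = aln.base_codes()[:, aln.columns(column_range)]
    counts = np.stack([(codes == i).sum(axis=0) for i in range(4)])  # (4, L)
    return int(((counts >= 2).sum(axis=0) >= 2).sum())


def sic_from_counts(pi_sites: int, length_bp: int) -> float:
    """Standardized information content: PI sites per kilobase, to 2 decimals."""
    if length_bp <= 0:
        raise ValueError("alignment length must be positive")
    return round(1000.0 * pi_sites / length_bp, 2)


def sic(aln: Alignment, column_range: Optional[Tuple[int, int]] = None) -> float:
    """SIC of an alignment (or of a 1-based inclusive column range within it)."""
    sl = aln.columns(column_range)
    length = sl.stop - sl.start
    return sic_from_counts(count_parsimony_informative(aln, column_range), length)


def p_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Uncorrected pairwise p-distances with pairwise deletion of missing data."""
    if aln.n_taxa < 2:
        raise ValueError("need at least two sequences")
    codes = aln.base_codes()
    n = aln.n_taxa
    d = np.zeros((n, n))
    valid = codes != 255
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                d[i, j] = d[j, i] = np.nan
                continue
            diff = int((codes[i][both] != codes[j][both]).sum())
            d[i, j] = d[j, i] = diff / m
    return DistanceMatrix(labels=list(aln.taxa), values=d)


def _jc69(p: float, gamma_shape: Optional[float] = None) -> float:
    if p >= 0.75:
        return np.nan
    if gamma_shape is None:
        return -0.75 * np.log(1.0 - 4.0 * p / 3.0)
    # gamma-rate generalisation: -log(w) -> a * (w^(-1/a) - 1)
    a = gamma_shape
    return 0.75 * a * ((1.0 - 4.0 * p / 3.0) ** (-1.0 / a) - 1.0)


def _transition_transversion(codes_i, codes_j) -> Tuple[float, float, int]:
    both = (codes_i != 255) & (codes_j != 255)
    a, b = codes_i[both], codes_j[both]
    m = int(both.sum())
    if m == 0:
        return np.nan, np.nan, 0
    diff = a != b
    # purines {A=0, G=2}, pyrimidines {C=1, T=3}: a transition stays within a class
    transition = diff & ((a % 2) == (b % 2))
    p = int(transition.sum()) / m
    q = int(diff.sum()) / m - p
    return p, q, m


def corrected_distance_matrix(
    aln: Alignment, model: str = "JC69", gamma_shape: Optional[float] = None
) -> DistanceMatrix:
    """Model-corrected pairwise distances (JC69, K80 or TN93 closed forms).

    With ``gamma_shape`` set, the JC69 correction uses its gamma-rates
    generalisation (each -log(w) term becomes a*(w^(-1/a) - 1)), accounting
    for among-site rate heterogeneity of shape ``a``.

    Pairs saturated beyond the model's validity bound get NaN; the count of
    such pairs is logged, mirroring the practice of dropping gap-rich markers
    from saturation analysis rather than inflating their regressions.
    """
    model = model.upper()
    if model not in ("JC69", "K80", "TN93"):
        raise ValueError(f"unknown correction model {model!r}")
    if gamma_shape is not None and model != "JC69":
        raise ValueError("gamma-corrected distances are implemented for JC69 only")
    codes = aln.base_codes()
    n = aln.n_taxa
    d = np.zeros((n, n))

    if model == "TN93":
        # empirical base frequencies over unambiguous cells
        flat = codes[codes != 255]
        freqs = np.array([(flat == i).mean() for i in range(4)])
        gA, gC, gG, gT = freqs
        gR, gY = gA + gG, gC + gT

    for i in range(n):
        for j in range(i + 1, n):
            if model == "JC69":
                both = (codes[i] != 255) & (codes[j] != 255)
                m = int(both.sum())
                if m == 0:
                    dij = np.nan
                else:
                    p = int((codes[i][both] != codes[j][both]).sum()) / m
                    dij = _jc69(p, gamma_shape)
            elif model == "K80":
                p, q, m = _transition_transversion(codes[i], codes[j])
                if m == 0:
                    dij = np.nan
                else:
                    w1, w2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
                    dij = (
                        np.nan
                        if w1 <= 0 or w2 <= 0
                        else -0.5 * np.log(w1) - 0.25 * np.log(w2)
                    )
            else:  # TN93
                both = (codes[i] != 255) & (codes[j] != 255)
                m = int(both.sum())
                if m == 0:
                    dij = np.nan
                else:
                    a, b = codes[i][both], codes[j][both]
                    diff = a != b
                    ag = diff & ((a == 0) | (a == 2)) & ((b == 0) | (b == 2))
                    ct = diff & ((a == 1) | (a == 3)) & ((b == 1) | (b == 3))
                    p1 = int(ag.sum()) / m  # purine transitions
                    p2 = int(ct.sum()) / m  # pyrimidine transitions
                    q = int(diff.sum()) / m - p1 - p2
                    k1 = 2.0 * gA * gG / gR
                    k2 = 2.0 * gC * gT / gY
                    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
                    w1 = 1.0 - p1 / k1 - q / (2.0 * gR)
                    w2 = 1.0 - p2 / k2 - q / (2.0 * gY)
                    w3 = 1.0 - q / (2.0 * gR * gY)
                    if w1 <= 0 or w2 <= 0 or w3 <= 0:
                        dij = np.nan
                    else:
                        dij = -k1 * np.log(w1) - k2 * np.log(w2) - k3 * np.log(w3)
            d[i, j] = d[j, i] = dij

    result = DistanceMatrix(labels=list(aln.taxa), values=d)
    if result.n_undefined_pairs:
        logger.info(
            "%s correction undefined for %d of %d pairs",
            model, result.n_undefined_pairs, n * (n - 1) // 2,
        )
    return result
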