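"""Readers and writers for the file dialects the tool touches.

Supported dialects: aligned FASTA / A3M multiple sequence alignments,
CCMpred-style dense score matrices, RaptorX-style sparse ``i j score``
contact lists, PSI-BLAST ASCII PSSMs (``-out_ascii_pssm``), PDB ATOM
records, and CASP RR contact predictions.

Residue indices are 0-based everywhere inside the package; the sparse
score and RR dialects are 1-based on disk, converted at this boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: Alphabet used for column counting: the 20 amino acids plus the gap symbol.
ALPHABET = AMINO_ACIDS + GAP

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class FormatError(ValueError):
    """Raised when an input file does not follow its declared dialect."""


@dataclass
class MSA:
    """An aligned set of homologous sequences.

    ``sequences`` hold uppercase residue characters over the 20 amino acids
    plus the gap ``-``; any other character has been mapped to ``X``, which
    downstream statistics treat as a gap.
    """

    sequences: list[str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise FormatError("MSA has no sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise FormatError(f"ragged MSA: row lengths {sorted(lengths)}")
        if self.cols < 1:
            raise FormatError("MSA has zero columns")

    @property
    def rows(self) -> int:
        return len(self.sequences)

    @property
    def cols(self) -> int:
        return len(self.sequences[0])

    def column(self, i: int) -> str:
        return "".join(s[i] for s in self.sequences)


@dataclass
class ScoreMatrix:
    """A symmetric L x L matrix of real-valued contact scores."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise FormatError(f"score matrix is not square: {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise FormatError("score matrix contains non-finite entries")
        # Distances are symmetric, so scores are forced symmetric at load.
        self.values = (self.values + self.values.T) / 2.0

    @property
    def L(self) -> int:
        return self.values.shape[0]


@dataclass
class PSSMProfile:
    """Position-specific scoring matrix: one 20-value log-odds row per residue."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise FormatError(f"PSSM must be L x 20, got {self.scores.shape}")
        if self.scores.shape[0] == 0:
            raise FormatError("PSSM has zero residues")

    @property
    def L(self) -> int:
        return self.scores.shape[0]


@dataclass
class ResidueChain:
    """A peptide with one representative-atom coordinate per residue.

    The representative atom is C-beta, falling back to C-alpha for glycine
    (or any residue whose C-beta is missing).
    """

    sequence: str
    coords: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.sequence), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match sequence "
                f"length {len(self.sequence)}"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")

    @property
    def L(self) -> int:
        return len(self.sequence)


def _canonical_residues(seq: str) -> str:
    out = []
    for ch in seq.upper().replace(".", GAP):
        out.append(ch if ch in ALPHABET else "X")
    return "".join(out)


def parse_msa(path: str | Path) -> MSA:
    """Read an aligned FASTA or A3M file.

    A3M lowercase characters mark insertions relative to the alignment's
    match columns and are deleted before the equal-length check, per the
    A3M convention.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise FormatError(f"empty alignment file: {path}")
    records: list[str] = []
    current: list[str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(("#", ";")):
            continue
        if line.startswith(">"):
            if current is not None:
                records.append("".join(current))
            current = []
        else:
            if current is None:
                # headerless input: treat each line as one aligned row
                records.append(line)
            else:
                current.append(line)
    if current is not None:
        records.append("".join(current))
    sequences = []
    for rec in records:
        rec = "".join(ch for ch in rec if not ch.islower())
        sequences.append(_canonical_residues(rec))
    return MSA(sequences)


def write_msa(msa: MSA, path: str | Path) -> None:
    """Serialize an MSA as aligned FASTA."""
    with open(path, "w") as fh:
        for k, seq in enumerate(msa.sequences):
            fh.write(f">seq{k}\n{seq}\n")


def parse_score_matrix(
    path: str | Path, dialect: str = "dense", L: int | None = None
) -> ScoreMatrix:
    """Read a rough contact score matrix.

    ``dense`` is the CCMpred text dialect: L whitespace-separated rows of L
    floats. ``sparse`` is the RaptorX-style contact list: lines
    ``i j score`` with 1-based ``i < j``; unlisted pairs are 0 and entries
    are mirrored. ``L`` is required for the sparse dialect.
    """
    path = Path(path)
    if dialect == "dense":
        try:
            values = np.loadtxt(path, dtype=float, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"non-numeric token in {path}: {exc}") from exc
        if values.shape[0] != values.shape[1]:
            raise FormatError(f"dense matrix is not square: {values.shape}")
        if L is not None and values.shape[0] != L:
            raise FormatError(f"expected L={L}, file has L={values.shape[0]}")
        return ScoreMatrix(values)
    if dialect == "sparse":
        if L is None:
            raise ValueError("sparse dialect requires L")
        values = np.zeros((L, L), dtype=float)
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            tokens = line.split()
            if len(tokens) < 3:
                raise FormatError(f"{path}:{lineno}: expected 'i j score'")
            try:
                i, j = int(tokens[0]), int(tokens[1])
                score = float(tokens[-1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric token") from exc
            if not (1 <= i <= L and 1 <= j <= L):
                raise FormatError(f"{path}:{lineno}: index outside [1, {L}]")
            values[i - 1, j - 1] = score
            values[j - 1, i - 1] = score
        return ScoreMatrix(values)
    raise ValueError(f"unknown score-matrix dialect: {dialect!r}")


def write_score_matrix(matrix: ScoreMatrix, path: str | Path) -> None:
    """Write a score matrix in the dense (CCMpred-style) text dialect."""
    np.savetxt(path, matrix.values, fmt="%.6f")


def write_sparse_scores(matrix: ScoreMatrix, path: str | Path) -> int:
    """Write all i < j entries as 1-based ``i j score`` lines."""
    n = 0
    with open(path, "w") as fh:
        for i in range(matrix.L):
            for j in range(i + 1, matrix.L):
                fh.write(f"{i + 1} {j + 1} {matrix.values[i, j]:.6f}\n")
                n += 1
    return n


def parse_pssm_ascii(path: str | Path) -> PSSMProfile:
    """Read a PSI-BLAST ``-out_ascii_pssm`` file.

    After the header, each residue line starts with the residue index and
    one-letter code followed by 20 integer log-odds columns (the second
    block of 20 percentage columns and the trailing statistics lines are
    ignored).
    """
    rows: list[list[float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        tokens = line.split()
        if len(tokens) < 2:
            continue
        # residue lines are "<index> <aa> <20 log-odds> ..."
        if not tokens[0].isdigit():
            continue
        if len(tokens[1]) != 1 or not tokens[1].isalpha():
            continue
        numeric = tokens[2:]
        if len(numeric) < 20:
            raise FormatError(
                f"{path}:{lineno}: residue line has {len(numeric)} numeric "
                "columns, need 20"
            )
        try:
            rows.append([float(tok) for tok in numeric[:20]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric log-odds") from exc
    if not rows:
        raise FormatError(f"no residue rows found in PSSM file {path}")
    return PSSMProfile(np.array(rows))


def parse_coordinates(path: str | Path, chain_id: str = "A") -> ResidueChain:
    """Extract the representative-atom trace of one chain from PDB ATOM records.

    Per residue the C-beta coordinate is used; residues lacking a C-beta
    (glycine in particular) fall back to C-alpha. Residues with neither are
    dropped with a warning and the sequence shortened accordingly. Only the
    first ATOM record per atom name is kept (altloc duplicates ignored).
    """
    residues: dict[tuple[str, int, str], dict[str, object]] = {}
    order: list[tuple[str, int, str]] = []
    chain_seen = False
    for line in Path(path).read_text().splitlines():
        if not line.startswith("ATOM"):
            continue
        if len(line) < 54:
            continue
        if line[21].strip() != chain_id:
            continue
        chain_seen = True
        atom = line[12:16].strip()
        resname = line[17:20].strip()
        try:
            resseq = int(line[22:26])
        except ValueError:
            continue
        icode = line[26].strip()
        key = (resname, resseq, icode)
        if key not in residues:
            residues[key] = {"name": resname}
            order.append(key)
        if atom in ("CA", "CB") and atom not in residues[key]:
            residues[key][atom] = np.array(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
    if not chain_seen:
        raise FormatError(f"chain {chain_id!r} not found in {path}")
    seq: list[str] = []
    coords: list[np.ndarray] = []
    for key in order:
        rec = residues[key]
        xyz = rec.get("CB", rec.get("CA"))
        if xyz is None:
            logger.warning(
                "residue %s%s has neither CB nor CA; dropped", key[0], key[1]
            )
            continue
        seq.append(_THREE_TO_ONE.get(str(rec["name"]), "X"))
        coords.append(np.asarray(xyz))
    if not seq:
        raise FormatError(f"chain {chain_id!r} in {path} has no usable residues")
    return ResidueChain("".join(seq), np.array(coords))


def write_pdb(chain: ResidueChain, path: str | Path, chain_id: str = "A") -> None:
    """Write the representative-atom trace as minimal PDB ATOM records.

    Glycine residues get a CA record (their representative atom), every
    other residue a CB record, so :func:`parse_coordinates` round-trips.
    """
    one_to_three = {v: k for k, v in _THREE_TO_ONE.items()}
    with open(path, "w") as fh:
        serial = 1
        for idx, (aa, xyz) in enumerate(zip(chain.sequence, chain.coords), start=1):
            resname = one_to_three.get(aa, "ALA")
            atom = "CA" if aa == "G" else "CB"
            fh.write(
                f"ATOM  {serial:>5} {atom:^4} {resname:>3} {chain_id}{idx:>4}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00\n"
            )
            serial += 1
        fh.write("TER\nEND\n")


def write_rr(pred: ScoreMatrix, path: str | Path) -> int:
    """Write a CASP RR-style contact prediction file.

    One line ``i j 0 8 p`` per unordered pair with 1-based ``i < j``,
    sorted by descending probability then ascending (i, j); the fixed
    ``0 8`` field pair is the distance window of the 8 angstrom contact
    definition. Returns the number of lines written.
    """
    values = pred.values
    if values.min() < 0.0 or values.max() > 1.0:
        raise ValueError("RR probabilities must lie in [0, 1]")
    iu, ju = np.triu_indices(pred.L, k=1)
    p = values[iu, ju]
    order = np.lexsort((ju, iu, -p))
    with open(path, "w") as fh:
        for idx in order:
            fh.write(f"{iu[idx] + 1} {ju[idx] + 1} 0 8 {p[idx]:.6f}\n")
    return len(order)
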