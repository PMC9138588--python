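"""Numerical characterization of drugs and target proteins.

Drugs
    881-bit PubChem substructure fingerprints: bit *i* flags the
    presence of the *i*-th predefined molecular fragment.  PubChem
    distributes them Base64-encoded; the dialect adopted here is a
    4-byte big-endian bit-count prefix (must equal 881) followed by the
    bits packed most-significant-bit first, trailing pad bits zero.

Proteins
    PSI-BLAST position-specific scoring matrices (PSSMs): an H x 20
    matrix of per-residue log-odds substitution scores, H the protein
    length, encoding evolutionary conservation.  The log-odds block is
    used (not the redundant weighted-percentage block).

Because proteins vary in length, the H x 20 profile is mapped to a
length-invariant 20 x 20 matrix (Theta^T Theta) / H — the normalized
cross-product of the amino-acid score columns — which serves as the
single-channel input image of the convolutional extractor.  A 2-D PCA
projection of those matrices is provided as an alternative
(ablation-style) descriptor, and drug/protein features are fused by
concatenation.
"""

from __future__ import annotations

import base64
import binascii
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParseError, ShapeError, WrongFingerprintTypeError

__all__ = [
    "FP_NBITS",
    "AA_ORDER",
    "Fingerprint",
    "PSSM",
    "decode_pubchem_fingerprint",
    "encode_pubchem_fingerprint",
    "parse_pssm",
    "format_pssm",
    "pssm_to_fixed",
    "two_dpca_features",
    "fuse_features",
    "load_fingerprint_table",
    "load_pssm_dir",
]

FP_NBITS = 881

# PSI-BLAST column order of the 20 standard amino acids.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class Fingerprint:
    """An 881-bit binary substructure vector."""

    bits: np.ndarray

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.shape != (FP_NBITS,):
            raise ShapeError(f"fingerprint must have {FP_NBITS} bits, got {bits.shape}")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("fingerprint bits must be 0/1")
        object.__setattr__(self, "bits", bits)


@dataclass(frozen=True)
class PSSM:
    """Position-specific scoring matrix: H x 20 log-odds + residues."""

    scores: np.ndarray
    residues: str

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ShapeError(f"PSSM must be H x 20, got {scores.shape}")
        if scores.shape[0] < 1:
            raise ShapeError("PSSM must have at least one row")
        if scores.shape[0] != len(self.residues):
            raise ShapeError(
                f"{scores.shape[0]} score rows but {len(self.residues)} residues"
            )
        object.__setattr__(self, "scores", scores)

    @property
    def length(self) -> int:
        return self.scores.shape[0]


def decode_pubchem_fingerprint(b64: str) -> Fingerprint:
    """Decode a Base64 PubChem fingerprint string to its 881 bits.

    Decoded bytes are a 4-byte big-endian bit count (which must be 881)
    followed by the bit data packed MSB-first; pad bits in the final
    byte must be zero.
    """
    try:
        raw = base64.b64decode(b64, validate=True)
    except (binascii.Error, ValueError) as exc:
        raise ParseError(f"invalid Base64 fingerprint: {exc}") from exc
    if len(raw) < 4:
        raise ParseError("fingerprint payload shorter than its 4-byte length prefix")
    nbits = int.from_bytes(raw[:4], "big")
    if nbits != FP_NBITS:
        raise WrongFingerprintTypeError(
            f"bit-count prefix is {nbits}, expected the {FP_NBITS}-bit PubChem key"
        )
    nbytes = (FP_NBITS + 7) // 8
    data = raw[4:]
    if len(data) != nbytes:
        raise ParseError(f"expected {nbytes} data bytes, got {len(data)}")
    all_bits = np.unpackbits(np.frombuffer(data, dtype=np.uint8))  # MSB-first
    if all_bits[FP_NBITS:].any():
        raise ParseError("non-zero padding bits after bit 880")
    return Fingerprint(bits=all_bits[:FP_NBITS].copy())


def encode_pubchem_fingerprint(fp: Fingerprint | np.ndarray) -> str:
    """Inverse of :func:`decode_pubchem_fingerprint` (exact round-trip)."""
    bits = fp.bits if isinstance(fp, Fingerprint) else Fingerprint(np.asarray(fp)).bits
    packed = np.packbits(bits)  # MSB-first, zero-padded
    payload = FP_NBITS.to_bytes(4, "big") + packed.tobytes()
    return base64.b64encode(payload).decode("ascii")


# --- PSI-BLAST ASCII PSSM ------------------------------------------------

_N_ROW_TOKENS = 44  # index + residue + 20 log-odds + 20 percentages + 2 floats


def parse_pssm(text: str) -> PSSM:
    """Parse PSI-BLAST ``-out_ascii_pssm`` output.

    Layout: three header lines (blank, description, amino-acid column
    header) followed by one line per residue with 44 whitespace-
    separated tokens: position index, residue letter, 20 log-odds
    integers, 20 weighted-percentage integers, and two trailing floats
    (information content, pseudocount weight).  Only the log-odds block
    and the residue string are retained.  Parsing stops at the first
    blank or non-matrix line after the data block (PSI-BLAST appends
    Lambda/K statistics there).
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise ParseError("PSSM file too short: missing header")

    rows: list[list[float]] = []
    residues: list[str] = []
    for line in lines[3:]:
        tokens = line.split()
        if not tokens or not tokens[0].isdigit():
            break  # end of matrix block
        row_idx = len(rows) + 1
        if len(tokens) != _N_ROW_TOKENS:
            raise ParseError(
                f"PSSM row {row_idx}: expected {_N_ROW_TOKENS} fields, "
                f"got {len(tokens)}"
            )
        if int(tokens[0]) != row_idx:
            raise ParseError(
                f"PSSM row {row_idx}: position index reads {tokens[0]}"
            )
        try:
            rows.append([float(v) for v in tokens[2:22]])
        except ValueError as exc:
            raise ParseError(f"PSSM row {row_idx}: non-numeric score: {exc}") from exc
        residues.append(tokens[1])

    if not rows:
        raise ParseError("PSSM file contains no matrix rows")
    return PSSM(scores=np.array(rows, dtype=float), residues="".join(residues))


def format_pssm(p: PSSM, percentages: np.ndarray | None = None) -> str:
    """Render a PSSM in the PSI-BLAST ASCII dialect parsed above.

    ``format_pssm`` / ``parse_pssm`` round-trip bit-exactly for integer
    log-odds.  The percentage block (not consumed on parse) defaults to
    zeros; the two trailing floats are written as 0.00.
    """
    if percentages is None:
        percentages = np.zeros_like(p.scores, dtype=int)
    header = " ".join(f"{a:>3}" for a in AA_ORDER)
    out = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "          " + header + "  " + header,
    ]
    for i in range(p.length):
        scores = " ".join(f"{int(v):>3d}" for v in p.scores[i])
        pcts = " ".join(f"{int(v):>3d}" for v in percentages[i])
        out.append(f"{i + 1:>5d} {p.residues[i]}  {scores}  {pcts}  0.00 0.00")
    out.append("")
    return "\n".join(out) + "\n"


def pssm_to_fixed(p: PSSM) -> np.ndarray:
    """Length-invariant 20 x 20 protein matrix (Theta^T Theta) / H.

    Equivalently the mean over residues of the outer product of each
    residue's 20 log-odds scores with itself; symmetric by
    construction and invariant to residue-row permutation.
    """
    theta = p.scores
    return theta.T @ theta / p.length


def two_dpca_basis(samples: list[np.ndarray], k: int) -> np.ndarray:
    """Leading-k eigenvector basis (20 x k) of the 2DPCA image covariance.

    G = (1/n) * sum_i (A_i - Abar)^T (A_i - Abar); eigenvectors are
    ordered by descending eigenvalue with a deterministic sign
    convention (largest-magnitude component positive), so the basis
    does not depend on sample ordering.
    """
    if k > 20 or k < 1:
        raise ShapeError(f"k must be in [1, 20], got {k}")
    if len(samples) < 2:
        raise ShapeError("2DPCA needs at least 2 samples")
    stack = np.stack([np.asarray(a, dtype=float) for a in samples])
    if stack.shape[1:] != (20, 20):
        raise ShapeError(f"samples must be 20 x 20, got {stack.shape[1:]}")

    centered = stack - stack.mean(axis=0)
    g = np.einsum("nij,nik->jk", centered, centered) / len(samples)
    evals, evecs = np.linalg.eigh(g)  # ascending
    order = np.argsort(evals)[::-1][:k]
    basis = evecs[:, order]
    for j in range(basis.shape[1]):
        pivot = np.argmax(np.abs(basis[:, j]))
        if basis[pivot, j] < 0:
            basis[:, j] = -basis[:, j]
    return basis


def two_dpca_features(samples: list[np.ndarray], k: int) -> list[np.ndarray]:
    """Two-dimensional PCA feature vectors of 20 x 20 protein matrices.

    Unlike classical PCA, 2DPCA never flattens the input matrices: each
    sample is projected onto the k leading eigenvectors of the image
    covariance matrix, and the resulting 20 x k score matrix is
    flattened row-major into a length-20k feature vector.
    """
    basis = two_dpca_basis(samples, k)
    return [(np.asarray(a, dtype=float) @ basis).ravel() for a in samples]


def fuse_features(fp: Fingerprint, protein_feat: np.ndarray) -> np.ndarray:
    """Concatenate [protein features || fingerprint bits as reals]."""
    protein_feat = np.asarray(protein_feat, dtype=float).ravel()
    if not np.isfinite(protein_feat).all():
        raise ValueError("protein features contain non-finite values")
    return np.concatenate([protein_feat, fp.bits.astype(float)])


# --- file-level loaders ---------------------------------------------------


def load_fingerprint_table(path: str | Path) -> dict[str, Fingerprint]:
    """Read a two-column "drug_id<TAB>base64" fingerprint table."""
    table: dict[str, Fingerprint] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            table[tokens[0]] = decode_pubchem_fingerprint(tokens[1])
    return table


def load_pssm_dir(directory: str | Path, target_ids: list[str]) -> dict[str, PSSM]:
    """Load ``<target_id>.pssm`` files for every requested target."""
    directory = Path(directory)
    out: dict[str, PSSM] = {}
    for tid in target_ids:
        f = directory / f"{tid}.pssm"
        if not f.exists():
            raise ParseError(f"missing PSSM file for target {tid!r}: {f}")
        out[tid] = parse_pssm(f.read_text(encoding="utf-8"))
    return out
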