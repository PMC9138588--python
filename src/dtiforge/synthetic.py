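"""Synthetic fixtures emulating the three input families.

Real runs need three external artifacts: an interaction pair list, a
Base64 fingerprint table, and one PSI-BLAST ASCII PSSM per target.
The generators here produce all three in the exact external formats,
with an optional *planted* signal so that recovery of a known
association pattern can be asserted end-to-end.

Planted construction
    Every drug and every target carries a latent binary class bit
    (exactly half of each universe is 1).  A pair is drawn into the
    positive set with weight (1 + s) when the two bits agree and
    (1 - s) when they disagree, s = ``signal_strength``: at s = 0
    positives are uniform (no signal), at s = 1 positives are purely
    agreeing pairs.  The bits also shift the observable features —
    bit-1 drugs get denser fingerprints, bit-1 targets get a positive
    mean shift on their PSSM log-odds — so the label structure is
    recoverable from the features exactly when s > 0.

    The default universe is 32 x 32 with 500 positives: agreeing pairs
    then number ~512, so at s = 1 the balanced negative sample is
    almost purely disagreeing pairs and a near-perfect classifier is
    achievable; shrinking the universe or raising n_positives raises
    the irreducible label noise.

What this does *not* emulate: real KEGG/DrugBank marginal statistics,
correlated substructure bits, realistic PSSM column structure, or
homology between targets.  Passing end-to-end tests on planted data
shows the pipeline recovers a strong low-rank association signal, not
that it matches benchmark accuracy on curated data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datasets import GoldStandardDataset
from .descriptors import FP_NBITS, AA_ORDER, Fingerprint, PSSM, \
    encode_pubchem_fingerprint, format_pssm
from .errors import SamplingInfeasibleError

__all__ = [
    "PlantedConfig",
    "PlantedData",
    "gen_fingerprints",
    "gen_pssm",
    "gen_planted_dataset",
    "write_fixture_dir",
]

PSSM_MIN, PSSM_MAX = -10, 12  # typical PSI-BLAST log-odds range


@dataclass(frozen=True)
class PlantedConfig:
    """Study conditions for one synthetic dataset."""

    n_drugs: int = 32
    n_targets: int = 32
    n_positives: int = 500
    signal_strength: float = 1.0
    seed: int = 0
    # feature-shift magnitudes at full signal
    base_density: float = 0.2
    density_shift: float = 0.3
    pssm_mean_shift: float = 2.0
    min_length: int = 80
    max_length: int = 200

    def __post_init__(self):
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")
        if self.n_positives > self.n_drugs * self.n_targets:
            raise SamplingInfeasibleError(
                "n_positives exceeds the drug x target cross-product"
            )


@dataclass
class PlantedData:
    """A generated dataset plus its feature files and latent structure."""

    dataset: GoldStandardDataset
    fingerprints: dict[str, tuple[Fingerprint, str]]   # id -> (bits, base64)
    pssms: dict[str, tuple[PSSM, str]]                 # id -> (matrix, ascii)
    drug_bits: np.ndarray
    target_bits: np.ndarray


def gen_fingerprints(
    n: int, density: float, seed: int, prefix: str = "D"
) -> list[tuple[str, Fingerprint, str]]:
    """n random fingerprints; each bit is 1 independently w.p. density."""
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        bits = (rng.random(FP_NBITS) < density).astype(np.uint8)
        fp = Fingerprint(bits=bits)
        out.append((f"{prefix}{i:05d}", fp, encode_pubchem_fingerprint(fp)))
    return out


def gen_pssm(length: int, seed: int, mean: float = 0.0) -> tuple[PSSM, str]:
    """A random PSSM of the given length plus its ASCII rendering.

    Log-odds are integers, drawn as a rounded normal (sd 3) around
    ``mean`` and clipped to the typical PSI-BLAST range [-10, 12];
    residues are uniform over the 20 standard amino acids.  The
    emitted text parses back to the identical matrix.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    scores = np.clip(np.rint(rng.normal(mean, 3.0, size=(length, 20))),
                     PSSM_MIN, PSSM_MAX)
    residues = "".join(rng.choice(list(AA_ORDER), size=length))
    p = PSSM(scores=scores, residues=residues)
    return p, format_pssm(p)


def _balanced_bits(n: int, rng: np.random.Generator) -> np.ndarray:
    bits = np.zeros(n, dtype=int)
    bits[: n // 2] = 1
    return rng.permutation(bits)


def gen_planted_dataset(cfg: PlantedConfig) -> PlantedData:
    """Dataset + features with a planted drug/target class-bit signal."""
    rng = np.random.default_rng(cfg.seed)
    s = cfg.signal_strength

    drug_ids = [f"D{i:05d}" for i in range(cfg.n_drugs)]
    target_ids = [f"hsa{j:05d}" for j in range(cfg.n_targets)]
    drug_bits = _balanced_bits(cfg.n_drugs, rng)
    target_bits = _balanced_bits(cfg.n_targets, rng)

    agree = (drug_bits[:, None] == target_bits[None, :]).ravel()
    weights = np.where(agree, 1.0 + s, 1.0 - s)
    if np.count_nonzero(weights) < cfg.n_positives:
        raise SamplingInfeasibleError(
            f"only {np.count_nonzero(weights)} pairs have positive sampling "
            f"weight but {cfg.n_positives} positives requested"
        )
    chosen = rng.choice(
        cfg.n_drugs * cfg.n_targets,
        size=cfg.n_positives,
        replace=False,
        p=weights / weights.sum(),
    )
    positives = {
        (drug_ids[int(c) // cfg.n_targets], target_ids[int(c) % cfg.n_targets])
        for c in chosen
    }
    ds = GoldStandardDataset(
        name=f"planted-s{s:g}-seed{cfg.seed}",
        drug_ids=drug_ids,
        target_ids=target_ids,
        positives=positives,
    )

    fingerprints: dict[str, tuple[Fingerprint, str]] = {}
    for i, did in enumerate(drug_ids):
        density = cfg.base_density + cfg.density_shift * s * drug_bits[i]
        bits = (rng.random(FP_NBITS) < density).astype(np.uint8)
        fp = Fingerprint(bits=bits)
        fingerprints[did] = (fp, encode_pubchem_fingerprint(fp))

    pssms: dict[str, tuple[PSSM, str]] = {}
    for j, tid in enumerate(target_ids):
        length = int(rng.integers(cfg.min_length, cfg.max_length + 1))
        mean = cfg.pssm_mean_shift * s * target_bits[j]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        pssms[tid] = gen_pssm(length, seed=sub_seed, mean=mean)

    return PlantedData(
        dataset=ds,
        fingerprints=fingerprints,
        pssms=pssms,
        drug_bits=drug_bits,
        target_bits=target_bits,
    )


def write_fixture_dir(data: PlantedData, out_dir: str | Path) -> None:
    """Materialize pairs.tsv, fp.tsv and pssm/<id>.pssm under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "pairs.tsv", "w", encoding="utf-8") as fh:
        for d, t in sorted(data.dataset.positives):
            fh.write(f"{d}\t{t}\n")
    with open(out_dir / "fp.tsv", "w", encoding="utf-8") as fh:
        for did in data.dataset.drug_ids:
            fh.write(f"{did}\t{data.fingerprints[did][1]}\n")
    pssm_dir = out_dir / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    for tid in data.dataset.target_ids:
        (pssm_dir / f"{tid}.pssm").write_text(data.pssms[tid][1], encoding="utf-8")
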