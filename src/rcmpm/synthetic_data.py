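"""Desk-scale synthetic fixtures with the statistical structure the method assumes.

The generator produces toy proteins end to end: a compact self-avoiding 3D
chain (fixed 3.8 A virtual bonds, 3.5 A clash distance, a tunable
compactness bias so chains of L >= 30 form long-range contacts), a
multiple sequence alignment whose contacting column pairs co-vary with
tunable coupling strength (the signal mutual information detects), a rough
score map obtained by corrupting the true contact map with Gaussian noise,
and 3-class secondary-structure / solvent-accessibility profiles derived
from the toy geometry (a documented geometric convention, not DSSP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from rcmpm.contact_geometry import ContactMap, distance_matrix, true_contact_map
from rcmpm.io_formats import AMINO_ACIDS, MSA, ResidueChain, ScoreMatrix
from rcmpm.seq_features import StructureProfile

logger = logging.getLogger(__name__)

BOND_LENGTH = 3.8  # A, virtual bond between consecutive representative atoms
CLASH_DISTANCE = 3.5  # A, minimum distance between non-neighbour residues


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic benchmark.

    ``coupling`` is the fraction of alignment rows whose contacting column
    pairs are drawn from a joint 2-symbol code; ``noise`` the standard
    deviation of the Gaussian corruption of the rough map.
    """

    L_range: tuple[int, int] = (26, 60)
    n_proteins: int = 5
    msa_depth: int = 200
    coupling: float = 0.8
    noise: float = 0.3
    seed: int = 0
    compactness: float = 0.5

    def __post_init__(self) -> None:
        if self.L_range[0] < 2 or self.L_range[1] < self.L_range[0]:
            raise ValueError(f"invalid L_range {self.L_range}")
        if self.msa_depth < 1 or self.n_proteins < 1:
            raise ValueError("depths and protein counts must be >= 1")
        if not (0 <= self.coupling <= 1 and 0 <= self.noise <= 1):
            raise ValueError("coupling and noise must lie in [0, 1]")


@dataclass
class SyntheticProtein:
    """One full fixture; all components share L and derive from one seed."""

    chain: ResidueChain
    truth: ContactMap
    msa: MSA
    rough: ScoreMatrix
    profile: StructureProfile
    seed: int


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _attempt_chain(L: int, compactness: float, rng: np.random.Generator,
                   n_candidates: int = 30, max_backtracks: int = 80) -> np.ndarray | None:
    """Grow one chain; compactness is the probability of taking the most
    centroid-ward clash-free step instead of a random clash-free one."""
    coords = np.zeros((L, 3))
    coords[1] = BOND_LENGTH * _unit(rng.normal(size=3))
    i = 2
    backtracks = 0
    while i < L:
        dirs = rng.normal(size=(n_candidates, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        cands = coords[i - 1] + BOND_LENGTH * dirs
        # clash against all non-adjacent placed residues
        dists = np.linalg.norm(coords[None, : i - 1] - cands[:, None], axis=2)
        ok = (dists >= CLASH_DISTANCE).all(axis=1)
        if not ok.any():
            backtracks += 1
            if backtracks > max_backtracks:
                return None
            i = max(2, i - 3)
            continue
        free = np.nonzero(ok)[0]
        if rng.random() < compactness:
            centroid = coords[:i].mean(axis=0)
            pick = free[np.argmin(np.linalg.norm(cands[free] - centroid, axis=1))]
        else:
            pick = free[rng.integers(len(free))]
        coords[i] = cands[pick]
        i += 1
    return coords


def generate_chain(L: int, seed: int, compactness: float = 0.5) -> ResidueChain:
    """Compact self-avoiding random walk with 3.8 A steps.

    If a chain jams (no clash-free step after bounded retries) the whole
    attempt restarts from an incremented sub-seed, so the result is still a
    deterministic function of (L, seed, compactness).
    """
    if L < 2:
        raise ValueError("chain needs L >= 2")
    for attempt in range(200):
        rng = np.random.default_rng([seed, attempt])
        coords = _attempt_chain(L, compactness, rng)
        if coords is not None:
            if attempt > 0:
                logger.info("chain seed %s succeeded on sub-seed %d", seed, attempt)
            seq_idx = rng.integers(0, 20, size=L)
            sequence = "".join(AMINO_ACIDS[a] for a in seq_idx)
            return ResidueChain(sequence, coords)
    raise RuntimeError(f"failed to place chain of L={L} after 200 sub-seeds")


def generate_msa(truth: ContactMap, depth: int, coupling: float, seed: int) -> MSA:
    """Alignment with co-varying columns at contacting pairs.

    Background symbols are i.i.d. uniform over the 20 amino acids.
    Contacting pairs with sequence separation >= 6 are coupled: a fraction
    ``coupling`` of rows draws the two columns jointly from a fixed
    two-state code (a1,b1)/(a2,b2) picked per pair, so the columns carry
    mutual information. A column can only carry one code, so coupling is
    applied to a maximal disjoint set of contacting pairs, longest
    separations first (overlapping pairs would overwrite and erase each
    other's signal).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    L = truth.L
    enc = rng.integers(0, 20, size=(depth, L))
    iu, ju = np.nonzero(np.triu(truth.labels, k=6))
    order = np.argsort(-(ju - iu), kind="stable")
    used: set[int] = set()
    for idx in order:
        i, j = int(iu[idx]), int(ju[idx])
        if i in used or j in used:
            continue
        used.update((i, j))
        a = rng.choice(20, size=2, replace=False)
        b = rng.choice(20, size=2, replace=False)
        mask = rng.random(depth) < coupling
        state = rng.integers(0, 2, size=depth)
        enc[mask, i] = a[state[mask]]
        enc[mask, j] = b[state[mask]]
    sequences = ["".join(AMINO_ACIDS[s] for s in row) for row in enc]
    return MSA(sequences)


def corrupt_contact_map(truth: ContactMap, noise: float, seed: int) -> ScoreMatrix:
    """Rough map emulator: truth labels plus symmetric Gaussian noise,
    clamped to [0, 1]. noise = 0 returns the binary truth as scores."""
    if not 0 <= noise <= 1:
        raise ValueError("noise must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    L = truth.L
    eps = rng.normal(0.0, noise if noise > 0 else 1.0, size=(L, L))
    eps = np.triu(eps) + np.triu(eps, k=1).T  # symmetric, N(0, noise) entries
    if noise == 0:
        eps = np.zeros((L, L))
    scores = np.clip(truth.labels.astype(float) + eps, 0.0, 1.0)
    return ScoreMatrix(scores)


def structure_profile_from_chain(chain: ResidueChain) -> StructureProfile:
    """Geometric 3-class SS/SA heuristic of the toy generator.

    Secondary structure from the span of a 5-residue window of the
    representative-atom trace (curled -> H, extended -> E, else C; chain
    ends -> C); solvent accessibility from the neighbour count within 10 A
    (>= 12 buried, <= 6 exposed, else medium).
    """
    L = chain.L
    dm = distance_matrix(chain)
    ss_labels = []
    for i in range(L):
        if i < 2 or i >= L - 2:
            ss_labels.append("C")
            continue
        span = dm[i - 2, i + 2]
        if span < 9.0:
            ss_labels.append("H")
        elif span > 12.5:
            ss_labels.append("E")
        else:
            ss_labels.append("C")
    neighbours = (dm < 10.0).sum(axis=1) - 1
    sa_labels = ["B" if c >= 12 else ("E" if c <= 6 else "M") for c in neighbours]
    from rcmpm.seq_features import encode_structure_profile

    return encode_structure_profile(ss_labels, sa_labels)


def make_protein(L: int, seed: int, config: GeneratorConfig) -> SyntheticProtein:
    """One full fixture from a single integer seed."""
    sub = np.random.SeedSequence(seed).generate_state(3)
    chain = generate_chain(L, int(sub[0]), config.compactness)
    truth = true_contact_map(chain)
    msa = generate_msa(truth, config.msa_depth, config.coupling, int(sub[1]))
    # make the chain sequence the alignment's first row so all views agree
    chain = ResidueChain(msa.sequences[0], chain.coords)
    rough = corrupt_contact_map(truth, config.noise, int(sub[2]))
    profile = structure_profile_from_chain(chain)
    return SyntheticProtein(
        chain=chain, truth=truth, msa=msa, rough=rough, profile=profile, seed=seed
    )


def make_dataset(config: GeneratorConfig) -> list[SyntheticProtein]:
    """n_proteins full fixtures with per-protein derived sub-seeds."""
    rng = np.random.default_rng(config.seed)
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_proteins)
    lengths = rng.integers(config.L_range[0], config.L_range[1] + 1,
                           size=config.n_proteins)
    return [
        make_protein(int(L), int(s), config) for L, s in zip(lengths, seeds)
    ]
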