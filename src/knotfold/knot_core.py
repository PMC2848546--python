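"""Knotted-core localization and subchain knot fingerprints.

The knotted core is the minimal stretch of chain that stays knotted
under successive deletions from the termini: residues are removed one
at a time from the N-terminus (re-closing and re-classifying the
remainder after each cut) until the knot vanishes, then the same scan
runs from the C-terminus with the N-boundary fixed.  Because closure
of a truncated chain can occasionally thread the structure's remains
in an unlucky projection, every classification is a majority vote over
several projection seeds.  Core boundaries are reported in author
numbering and are a guideline, not a sharp object — single-residue
shifts are expected between closure conventions.

The knot fingerprint classifies every subchain on a stride grid and is
the object on which slipknots are defined: a chain whose full-length
closure is unknotted but which contains a knotted subchain.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .knot_detect import KnotLabel, classify_knot, close_chain, kmt_reduce
from .structures import BackboneChain

__all__ = ["KnotCore", "KnotFingerprint", "knotted_core", "knot_fingerprint",
           "is_slipknot", "classify_open_chain"]


class UnknottedChainError(ValueError):
    """Core scan requested on a chain whose closure is already trivial."""


@dataclass
class KnotCore:
    """Minimal knotted subchain, in author residue numbers."""

    start: int
    end: int
    core_knot: KnotLabel
    whole_chain_knot: KnotLabel
    start_index: int = 0  # positional indices into the chain
    end_index: int = 0


@dataclass
class KnotFingerprint:
    """Knot type of every subchain on a stride grid.

    ``entries`` maps positional ``(i, j)`` (j exclusive) to knot name;
    ``author_entries`` gives the same keyed by author residue numbers.
    """

    stride: int
    n_residues: int
    entries: dict[tuple[int, int], str] = field(default_factory=dict)
    author_entries: dict[tuple[int, int], str] = field(default_factory=dict)

    @property
    def full_chain_name(self) -> str:
        return self.entries[(0, self.n_residues)]

    def knotted_subchains(self) -> list[tuple[int, int]]:
        return [k for k, v in self.entries.items()
                if v not in ("0_1", "unclassified") and k != (0, self.n_residues)]


def classify_open_chain(coords: np.ndarray, seeds) -> KnotLabel:
    """Close an open chain and classify it by majority vote over seeds.

    The closure is recomputed for each seed's projection; the chain's
    own centre of mass (of the coordinates given, i.e. of the subchain
    when truncated) anchors the closure rays.
    """
    curve = kmt_reduce(close_chain(coords))
    votes = [classify_knot(curve, seed=int(s), reduce_first=False)
             for s in np.atleast_1d(seeds)]
    count = Counter(lab.name for lab in votes)
    winner, _ = count.most_common(1)[0]
    for lab in votes:
        if lab.name == winner:
            return lab
    raise AssertionError("unreachable")


def _vote_seeds(seed: int, n_votes: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**31 - 1, size=n_votes)


def knotted_core(chain: BackboneChain, seed: int = 0, n_votes: int = 5) -> KnotCore:
    """Locate the minimal subchain that stays knotted under terminal deletions.

    Scans the N-terminus first (last knotted start defines the core
    start), then the C-terminus with the start fixed.  Each truncation
    is re-closed about its own centre of mass and classified by
    majority vote over ``n_votes`` projection seeds derived from
    ``seed``.
    """
    seeds = _vote_seeds(seed, n_votes)
    whole = classify_open_chain(chain.coords, seeds)
    if not whole.is_knotted or whole.name == "unclassified":
        raise UnknottedChainError(f"no knot to core: whole chain is {whole.name}")

    def knotted(i, j):
        lab = classify_open_chain(chain.coords[i:j], seeds)
        return lab.is_knotted and lab.name != "unclassified"

    # alternate N- and C-terminal deletion scans until neither boundary
    # moves: the result is minimal on both sides simultaneously (a single
    # N-then-C pass can leave the N side trimmable again once the C side
    # has been shortened)
    n = len(chain)
    start_idx, end_idx = 0, n
    for _ in range(6):
        moved = False
        i = start_idx
        while i + 3 < end_idx and knotted(i + 1, end_idx):
            i += 1
            moved = moved or i != start_idx
        start_idx = i
        j = end_idx
        while j - 3 > start_idx and knotted(start_idx, j - 1):
            j -= 1
            moved = moved or j != end_idx
        end_idx = j
        if not moved:
            break

    core_label = classify_open_chain(chain.coords[start_idx:end_idx], seeds)
    return KnotCore(
        start=chain.residues[start_idx][0],
        end=chain.residues[end_idx - 1][0],
        core_knot=core_label,
        whole_chain_knot=whole,
        start_index=start_idx,
        end_index=end_idx,
    )


def knot_fingerprint(chain: BackboneChain, stride: int = 5, seed: int = 0,
                     min_length: int = 10, n_votes: int = 1) -> KnotFingerprint:
    """Classify every subchain on a stride grid (plus the full chain)."""
    if stride < 1:
        raise ValueError("stride >= 1 required")
    seeds = _vote_seeds(seed, n_votes)
    n = len(chain)
    fp = KnotFingerprint(stride=stride, n_residues=n)
    starts = list(range(0, n, stride))
    ends = [min(e, n) for e in list(range(stride, n, stride)) + [n]]
    pairs = {(i, j) for i in starts for j in ends if j - i >= min_length}
    pairs.add((0, n))
    for i, j in sorted(pairs):
        lab = classify_open_chain(chain.coords[i:j], seeds)
        fp.entries[(i, j)] = lab.name
        fp.author_entries[(chain.residues[i][0], chain.residues[j - 1][0])] = lab.name
    return fp


def is_slipknot(fp: KnotFingerprint) -> bool:
    """True iff the whole chain is unknotted but some subchain is knotted."""
    return fp.full_chain_name == "0_1" and bool(fp.knotted_subchains())
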