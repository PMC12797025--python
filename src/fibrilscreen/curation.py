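"""Scaffold-aware library triage against three reference chemotypes.

Each library molecule is assigned to its nearest reference scaffold by
Tanimoto similarity; molecules scoring below a cutoff (default 0.2)
against all three references are "alternative" chemical space. The
prospective set mixes top-similarity picks (round-robin across the three
chemotypes) with a seeded uniform sample of alternatives.

The pass over the library is streaming: bounded-size heaps hold the
high-similarity candidates and a reservoir holds the alternative sample,
so the same code scales from test libraries to catalog-sized inputs.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from fibrilscreen.chem import (
    FingerprintBits,
    FingerprintConfig,
    Molecule,
    morgan_fingerprint,
    tanimoto,
)

HIGH_SIMILARITY = "high_similarity"
LOW_SIMILARITY = "low_similarity"


@dataclass(frozen=True)
class ReferenceSet:
    """Ordered named reference scaffolds; order breaks nearest-chemotype ties."""

    names: tuple[str, ...]
    molecules: tuple[Molecule, ...]
    fingerprints: tuple[FingerprintBits, ...]

    @classmethod
    def from_molecules(
        cls,
        named: Sequence[tuple[str, Molecule]],
        cfg: FingerprintConfig = FingerprintConfig(),
    ) -> "ReferenceSet":
        names = tuple(n for n, _ in named)
        mols = tuple(m for _, m in named)
        fps = tuple(morgan_fingerprint(m, cfg) for m in mols)
        return cls(names=names, molecules=mols, fingerprints=fps)

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class SimilarityProfile:
    compound_id: str
    scores: tuple[float, ...]  # per reference, in reference order
    nearest_reference: str
    nearest_score: float
    is_alternative: bool


@dataclass(frozen=True)
class CurationConfig:
    alt_cutoff: float = 0.2
    n_high: int = 14
    n_low: int = 16
    seed: int = 0

    @property
    def prospective_size(self) -> int:
        return self.n_high + self.n_low


@dataclass(frozen=True)
class ProspectiveSelection:
    """Selected compound ids with their rationale tag and profiles."""

    selected: tuple[tuple[str, str], ...]  # (compound_id, tag)
    profiles: dict[str, SimilarityProfile]

    def ids(self) -> list[str]:
        return [cid for cid, _ in self.selected]

    def ids_by_tag(self, tag: str) -> list[str]:
        return [cid for cid, t in self.selected if t == tag]


def assign_chemotype(
    fp: FingerprintBits,
    refs: ReferenceSet,
    compound_id: str = "",
    alt_cutoff: float = 0.2,
) -> SimilarityProfile:
    """Similarity profile of one fingerprint against the references.

    Nearest reference is the max-score one; exact ties go to the first
    reference in the fixed order. ``is_alternative`` iff every score is
    strictly below ``alt_cutoff``.
    """
    scores = tuple(tanimoto(fp, rf) for rf in refs.fingerprints)
    best = max(range(len(scores)), key=lambda i: (scores[i], -i))
    return SimilarityProfile(
        compound_id=compound_id,
        scores=scores,
        nearest_reference=refs.names[best],
        nearest_score=scores[best],
        is_alternative=all(s < alt_cutoff for s in scores),
    )


def profile_library(
    molecules: Iterable[Molecule],
    refs: ReferenceSet,
    cfg: FingerprintConfig = FingerprintConfig(),
    alt_cutoff: float = 0.2,
) -> Iterator[SimilarityProfile]:
    for mol in molecules:
        fp = morgan_fingerprint(mol, cfg)
        yield assign_chemotype(fp, refs, compound_id=mol.id, alt_cutoff=alt_cutoff)


def similarity_histogram(
    profiles: Sequence[SimilarityProfile],
    bin_width: float = 0.05,
    overlays: dict[str, Sequence[str]] | None = None,
) -> dict:
    """Per-reference binned counts of similarity scores.

    Bins are half-open [lo, hi) with the final bin closed at 1.0, so a
    score of exactly 1.0 is counted once. ``overlays`` maps a tag (e.g.
    "train", "prospective") to compound ids; their per-reference scores
    are emitted as tick positions for plotting.
    """
    if not (0 < bin_width <= 1):
        raise ValueError("bin_width must be in (0, 1]")
    if not profiles:
        return {"bin_edges": [], "counts": {}, "overlays": {}}
    n_refs = len(profiles[0].scores)
    ref_names = _reference_names(profiles)
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    counts = {}
    for i in range(n_refs):
        vals = np.array([p.scores[i] for p in profiles])
        hist, _ = np.histogram(vals, bins=edges)
        counts[ref_names[i]] = hist.tolist()
    overlay_out: dict[str, dict[str, list[float]]] = {}
    by_id = {p.compound_id: p for p in profiles}
    for tag, ids in (overlays or {}).items():
        overlay_out[tag] = {
            ref_names[i]: [by_id[c].scores[i] for c in ids if c in by_id]
            for i in range(n_refs)
        }
    return {"bin_edges": edges.tolist(), "counts": counts, "overlays": overlay_out}


def _reference_names(profiles: Sequence[SimilarityProfile]) -> list[str]:
    # recover reference order from any profile's nearest bookkeeping
    # (profiles store scores positionally; names come from the nearest
    # field of profiles achieving each max — fall back to indices)
    n = len(profiles[0].scores)
    names: list[str | None] = [None] * n
    for p in profiles:
        i = max(range(n), key=lambda j: (p.scores[j], -j))
        if names[i] is None:
            names[i] = p.nearest_reference
        if all(x is not None for x in names):
            break
    return [x if x is not None else f"ref{i}" for i, x in enumerate(names)]


def select_prospective(
    profiles: Iterable[SimilarityProfile],
    cfg: CurationConfig = CurationConfig(),
) -> ProspectiveSelection:
    """Pick the prospective set: n_high top-similarity compounds balanced
    round-robin across chemotypes, plus n_low alternatives sampled
    uniformly (seeded reservoir).

    Raises if either stratum cannot be filled, stating the shortfall.
    """
    heaps: dict[str, list] = {}
    kept_profiles: dict[str, SimilarityProfile] = {}
    reservoir: list[SimilarityProfile] = []
    rng = np.random.default_rng(cfg.seed)
    n_alt_seen = 0
    seen_ids: set[str] = set()
    ref_order: list[str] = []

    for p in profiles:
        if p.compound_id in seen_ids:
            raise ValueError(f"duplicate compound id {p.compound_id!r}")
        seen_ids.add(p.compound_id)
        if p.is_alternative:
            n_alt_seen += 1
            if len(reservoir) < cfg.n_low:
                reservoir.append(p)
            else:
                j = int(rng.integers(0, n_alt_seen))
                if j < cfg.n_low:
                    reservoir[j] = p
        else:
            ref = p.nearest_reference
            if ref not in heaps:
                heaps[ref] = []
                ref_order.append(ref)
            # min-heap of (score, tiebreak id) bounded at n_high per chemotype
            item = (p.nearest_score, p.compound_id)
            if len(heaps[ref]) < cfg.n_high:
                heapq.heappush(heaps[ref], item)
                kept_profiles[p.compound_id] = p
            elif item > heaps[ref][0]:
                _, evicted = heapq.heapreplace(heaps[ref], item)
                del kept_profiles[evicted]
                kept_profiles[p.compound_id] = p

    n_non_alt = sum(len(h) for h in heaps.values())
    if n_non_alt < cfg.n_high:
        raise ValueError(
            f"insufficient high-similarity candidates: need {cfg.n_high}, "
            f"have {n_non_alt}"
        )
    if n_alt_seen < cfg.n_low:
        raise ValueError(
            f"insufficient alternative candidates (<{cfg.alt_cutoff} to all "
            f"references): need {cfg.n_low}, have {n_alt_seen}"
        )

    # round-robin across chemotypes by descending nearest_score
    ranked = {
        ref: sorted(h, key=lambda t: (-t[0], t[1])) for ref, h in heaps.items()
    }
    order = sorted(ref_order)  # stable chemotype cycling order
    picks: list[tuple[str, str]] = []
    cursor = {ref: 0 for ref in order}
    while len(picks) < cfg.n_high:
        progressed = False
        for ref in order:
            if len(picks) >= cfg.n_high:
                break
            i = cursor[ref]
            if i < len(ranked[ref]):
                _, cid = ranked[ref][i]
                picks.append((cid, HIGH_SIMILARITY))
                cursor[ref] += 1
                progressed = True
        if not progressed:
            break

    low_sorted = sorted(reservoir, key=lambda p: p.compound_id)
    for p in low_sorted:
        picks.append((p.compound_id, LOW_SIMILARITY))
        kept_profiles[p.compound_id] = p

    selected_profiles = {cid: kept_profiles[cid] for cid, _ in picks}
    return ProspectiveSelection(selected=tuple(picks), profiles=selected_profiles)
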