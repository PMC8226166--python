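"""Interaction persistence: fraction of frames a residue pair is in contact.

Persistence is the fraction of trajectory frames in which a residue pair
is in (any-atom heavy-atom) close contact.  Reported interaction maps
keep pairs at or above a lower threshold, 10% of the simulation time by
default, label each entry intra- or intermolecular, and type it via the
salt-bridge classifier.  Fractions are kept as exact rationals
(frames-in-contact / total frames) so threshold comparisons at the 10%
boundary are exact.

Intramolecular pairs closer than three positions in sequence
(|i - j| <= 2) are excluded by default: such contacts are trivially
persistent consequences of backbone connectivity, not interactions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

from .contacts import (
    ContactSeries,
    InteractionType,
    PairKey,
    classify_pair,
    resolve_residue,
)
from .ptm import PeptideSpec

__all__ = [
    "MapEntry",
    "PersistenceMap",
    "persistence_fraction",
    "build_interaction_map",
    "count_intermolecular",
]


def _as_fraction(threshold) -> Fraction:
    """Interpret a threshold at its printed decimal value.

    A float literal like 0.10 denotes the decimal 1/10, not its binary
    representation (which is slightly above 1/10 and would wrongly exclude
    a pair in contact in exactly 10% of frames).
    """
    if isinstance(threshold, Fraction):
        return threshold
    if isinstance(threshold, int):
        return Fraction(threshold)
    return Fraction(repr(float(threshold)))


@dataclass(frozen=True)
class MapEntry:
    pair: PairKey
    scope: str  # "intramolecular" | "intermolecular"
    fraction: Fraction
    interaction: InteractionType

    @property
    def percent(self) -> float:
        return float(self.fraction) * 100.0


@dataclass
class PersistenceMap:
    """Thresholded, typed persistence entries sorted by descending fraction."""

    entries: tuple[MapEntry, ...]
    threshold: Fraction
    n_frames: int

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def intermolecular(self) -> tuple[MapEntry, ...]:
        return tuple(e for e in self.entries if e.scope == "intermolecular")

    def intramolecular(self) -> tuple[MapEntry, ...]:
        return tuple(e for e in self.entries if e.scope == "intramolecular")

    def to_records(self) -> list[dict]:
        return [
            {
                "chain_a": e.pair[0][0],
                "res_a": e.pair[0][1],
                "chain_b": e.pair[1][0],
                "res_b": e.pair[1][1],
                "scope": e.scope,
                "fraction": float(e.fraction),
                "percent": e.percent,
                "category": e.interaction.category,
                "donor_modified": e.interaction.donor_modified,
            }
            for e in self.entries
        ]

    def to_json(self, path=None, thin_at: float = 0.10, thick_at: float = 0.98):
        """JSON document for the linear interaction-diagram renderer.

        ``line_width`` maps persistence linearly from ``thin_at`` (thinnest)
        to ``thick_at`` (thickest), clipped to [0, 1].
        """
        span = thick_at - thin_at
        records = []
        for rec in self.to_records():
            w = (rec["fraction"] - thin_at) / span if span > 0 else 1.0
            rec["line_width"] = min(1.0, max(0.0, w))
            records.append(rec)
        doc = {
            "threshold": float(self.threshold),
            "n_frames": self.n_frames,
            "entries": records,
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return doc

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "chain_a\tres_a\tchain_b\tres_b\tscope\tfraction\tcategory\n"
            )
            for e in self.entries:
                fh.write(
                    f"{e.pair[0][0]}\t{e.pair[0][1]}\t{e.pair[1][0]}\t"
                    f"{e.pair[1][1]}\t{e.scope}\t"
                    f"{float(e.fraction):.6f}\t{e.interaction.category}\n"
                )


def persistence_fraction(series: ContactSeries, pair: PairKey) -> Fraction:
    """Exact fraction of frames in which ``pair`` is in close contact."""
    return Fraction(series.frames_in_contact(pair), series.n_frames)


def build_interaction_map(
    series: ContactSeries,
    topology: Mapping[str, PeptideSpec],
    threshold=Fraction(1, 10),
    intra_exclusion: int = 2,
) -> PersistenceMap:
    """Threshold the contact series into a typed persistence map.

    Intermolecular pairs are all residue pairs across the two chains;
    intramolecular pairs exclude sequence neighbours with
    ``|i - j| <= intra_exclusion``.  Entries with persistence >= threshold
    (inclusive) are kept, typed via :func:`classify_pair`, and sorted by
    descending persistence (pair key as tie-break).
    """
    thr = _as_fraction(threshold)
    entries = []
    for pair in series.pair_incidence:
        (chain_a, res_a), (chain_b, res_b) = pair
        if chain_a == chain_b:
            if not series.include_intra:
                continue
            if abs(res_a - res_b) <= intra_exclusion:
                continue
            scope = "intramolecular"
        else:
            scope = "intermolecular"
        frac = persistence_fraction(series, pair)
        if frac < thr:
            continue
        interaction = classify_pair(
            resolve_residue(topology, pair[0]), resolve_residue(topology, pair[1])
        )
        entries.append(MapEntry(pair=pair, scope=scope, fraction=frac,
                                interaction=interaction))
    entries.sort(key=lambda e: (-e.fraction, e.pair))
    return PersistenceMap(entries=tuple(entries), threshold=thr,
                          n_frames=series.n_frames)


def count_intermolecular(pmap: PersistenceMap) -> int:
    """Number of intermolecular interactions in the map (the paper-style n)."""
    return len(pmap.intermolecular())
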