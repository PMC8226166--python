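"""Heavy-atom close contacts, the N_cc statistic, and salt-bridge typing.

A close contact is a pair of heavy (non-hydrogen) atoms, one per chain,
at a distance strictly below the cutoff (default 4 Å).  ``N_cc`` counts
such inter-chain atom pairs per frame; its time average characterises how
extensively two peptides associate.  At residue granularity a pair of
residues is "in contact" in a frame when at least one of its heavy-atom
pairs is within the cutoff (the usual any-atom contact-map convention).

Residue-pair interactions are typed by residue identity and PTM state:
a contact between (possibly methylated) Arg or Lys and phospho-Ser/Thr is
labelled a salt bridge of the corresponding class.  Arginine-phosphate
bridges are the chemically strong class (bidentate guanidinium-phosphate
pairing); the classifier nevertheless defines all four R/K x pS/pT
classes so their (non-)occurrence can be counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.spatial import cKDTree

from .ptm import PeptideSpec, ResiduePTM
from .trajectory import Frame, Trajectory

__all__ = [
    "ResidueKey",
    "PairKey",
    "ContactSeries",
    "InteractionType",
    "frame_close_contacts",
    "compute_contact_series",
    "mean_ncc",
    "classify_pair",
    "min_residue_distances",
]

#: (chain_id, 1-based residue index)
ResidueKey = tuple[str, int]
#: unordered residue pair, stored sorted
PairKey = tuple[ResidueKey, ResidueKey]


def make_pair_key(a: ResidueKey, b: ResidueKey) -> PairKey:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class InteractionType:
    """Classification of a residue-pair interaction."""

    category: str  # R_pS_saltbridge | R_pT_saltbridge | K_pS_saltbridge | K_pT_saltbridge | other_contact
    donor_modified: bool = False
    acceptor: str = ""


@dataclass
class ContactSeries:
    """Per-frame close-contact incidence for a two-chain trajectory.

    ``per_frame_ncc[f]`` is the number of inter-chain heavy-atom pairs
    closer than ``cutoff`` in frame ``f``; ``pair_incidence[pair][f]`` is
    True when the residue pair is in (any-atom) contact in frame ``f``.
    Intra-chain residue pairs are included when the series was built with
    ``include_intra=True``; they never contribute to ``per_frame_ncc``.
    """

    per_frame_ncc: np.ndarray
    pair_incidence: dict[PairKey, np.ndarray]
    cutoff: float
    chain_ids: tuple[str, str]
    n_frames: int
    include_intra: bool = False

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("contact series needs at least one frame")
        if np.any(self.per_frame_ncc < 0):
            raise ValueError("negative close-contact count")

    def frames_in_contact(self, pair: PairKey) -> int:
        if pair not in self.pair_incidence:
            raise KeyError(f"unknown residue pair {pair!r}")
        return int(self.pair_incidence[pair].sum())


def _split_chains(frame: Frame):
    chains = frame.chain_ids()
    if len(chains) != 2:
        raise ValueError(
            f"frame {frame.frame_index}: contact analysis requires exactly "
            f"2 chains, found {len(chains)}"
        )
    a_id, b_id = sorted(chains)
    idx_a = [i for i, at in enumerate(frame.atoms) if at.chain_id == a_id]
    idx_b = [i for i, at in enumerate(frame.atoms) if at.chain_id == b_id]
    return a_id, b_id, idx_a, idx_b


def frame_close_contacts(
    frame: Frame, cutoff: float = 4.0, include_intra: bool = False
):
    """Close contacts of one heavy-atom frame.

    Returns ``(ncc, contact_pairs)`` where ``ncc`` counts inter-chain
    atom pairs with distance strictly below ``cutoff`` (each unordered
    pair once) and ``contact_pairs`` is the set of residue pairs with at
    least one such atom pair.  With ``include_intra=True`` the set also
    contains intra-chain residue pairs (``ncc`` stays inter-chain only).

    Uses a k-d tree neighbour query; the equivalent all-pairs double loop
    is the reference the implementation is validated against.
    """
    a_id, b_id, idx_a, idx_b = _split_chains(frame)
    coords = frame.coords
    tree_a = cKDTree(coords[idx_a])
    tree_b = cKDTree(coords[idx_b])

    ncc = 0
    pairs: set[PairKey] = set()
    neighbors = tree_a.query_ball_tree(tree_b, r=cutoff)
    for ia, hits in enumerate(neighbors):
        atom_a = frame.atoms[idx_a[ia]]
        for ib in hits:
            # query_ball_tree includes points at exactly r; the contact
            # definition is strict (< cutoff).
            d = np.linalg.norm(coords[idx_a[ia]] - coords[idx_b[ib]])
            if d < cutoff:
                ncc += 1
                atom_b = frame.atoms[idx_b[ib]]
                pairs.add(
                    make_pair_key(
                        (a_id, atom_a.residue_index), (b_id, atom_b.residue_index)
                    )
                )

    if include_intra:
        for cid, idx in ((a_id, idx_a), (b_id, idx_b)):
            tree = cKDTree(coords[idx])
            for i, j in tree.query_pairs(r=cutoff):
                d = np.linalg.norm(coords[idx[i]] - coords[idx[j]])
                if d >= cutoff:
                    continue
                ri = frame.atoms[idx[i]].residue_index
                rj = frame.atoms[idx[j]].residue_index
                if ri != rj:
                    pairs.add(make_pair_key((cid, ri), (cid, rj)))
    return ncc, pairs


def min_residue_distances(frame: Frame) -> dict[PairKey, float]:
    """Minimum heavy-atom distance for every inter-chain residue pair."""
    a_id, b_id, idx_a, idx_b = _split_chains(frame)
    coords = frame.coords
    res_a = np.array([frame.atoms[i].residue_index for i in idx_a])
    res_b = np.array([frame.atoms[i].residue_index for i in idx_b])
    diff = coords[idx_a][:, None, :] - coords[idx_b][None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    out: dict[PairKey, float] = {}
    for ra in np.unique(res_a):
        mask_a = res_a == ra
        for rb in np.unique(res_b):
            d = dist[mask_a][:, res_b == rb].min()
            out[make_pair_key((a_id, int(ra)), (b_id, int(rb)))] = float(d)
    return out


def compute_contact_series(
    traj: Trajectory,
    cutoff: float = 4.0,
    include_intra: bool = True,
    stride: int = 1,
) -> ContactSeries:
    """Close-contact incidence over all frames (optionally strided).

    The caller is expected to pass a heavy-atom trajectory
    (:func:`ptmdimer.trajectory.heavy_atom_view`).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    frames = traj.frames[::stride]
    n = len(frames)
    ncc = np.zeros(n, dtype=int)
    incidence: dict[PairKey, np.ndarray] = {}

    # Pre-register every residue pair so absent contacts are queryable.
    a_id, b_id = traj.chain_ids
    res_by_chain: dict[str, list[int]] = {a_id: [], b_id: []}
    for atom in frames[0].atoms:
        lst = res_by_chain[atom.chain_id]
        if not lst or lst[-1] != atom.residue_index:
            lst.append(atom.residue_index)
    for ra in res_by_chain[a_id]:
        for rb in res_by_chain[b_id]:
            incidence[make_pair_key((a_id, ra), (b_id, rb))] = np.zeros(n, dtype=bool)
    if include_intra:
        for cid in (a_id, b_id):
            resl = res_by_chain[cid]
            for i, ra in enumerate(resl):
                for rb in resl[i + 1 :]:
                    incidence[make_pair_key((cid, ra), (cid, rb))] = np.zeros(
                        n, dtype=bool
                    )

    for f, frame in enumerate(frames):
        count, pairs = frame_close_contacts(frame, cutoff, include_intra=include_intra)
        ncc[f] = count
        for pair in pairs:
            incidence[pair][f] = True
    return ContactSeries(
        per_frame_ncc=ncc,
        pair_incidence=incidence,
        cutoff=cutoff,
        chain_ids=(a_id, b_id),
        n_frames=n,
        include_intra=include_intra,
    )


def mean_ncc(series: ContactSeries) -> float:
    """Time-averaged number of inter-chain close contacts (the N_cc statistic)."""
    return float(series.per_frame_ncc.mean())


def classify_pair(res_a: ResiduePTM, res_b: ResiduePTM) -> InteractionType:
    """Type a residue-pair interaction.

    A salt-bridge class is assigned when one residue is phospho-Ser/Thr
    and the other is Arg or Lys in any methylation state;
    ``donor_modified`` flags a methylated basic partner.  Everything else
    is ``other_contact``.
    """
    for donor, acceptor in ((res_a, res_b), (res_b, res_a)):
        if donor.base in "RK" and donor.ptm != "ac" and acceptor.ptm == "ph" \
                and acceptor.base in "ST":
            category = f"{donor.base}_p{acceptor.base}_saltbridge"
            return InteractionType(
                category=category,
                donor_modified=donor.ptm in ("me1", "me2", "me3"),
                acceptor=f"{acceptor.base}-phos",
            )
    return InteractionType(category="other_contact")


def resolve_residue(topology: Mapping[str, PeptideSpec], key: ResidueKey) -> ResiduePTM:
    """Look up the PTM state of a (chain, residue-index) key in a topology."""
    chain, index = key
    spec = topology[chain]
    if not 1 <= index <= len(spec):
        raise KeyError(f"residue index {index} out of range for chain {chain}")
    return spec.residues[index - 1]
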