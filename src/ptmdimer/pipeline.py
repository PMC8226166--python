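"""End-to-end analysis pipeline: trajectory -> contacts -> persistence -> SASA.

`run_analysis` reads a two-chain multi-model PDB trajectory plus its
topology sidecar, restricts to heavy atoms, computes per-frame close
contacts and the N_cc average, builds the thresholded persistence map,
computes the buried-area statistic dA, and writes a report directory:

* ``summary.tsv`` / ``summary.json``  - dimer label, conformation, N_cc,
  dA, intermolecular interaction count (display precision mirrors the
  conventional table format: N_cc one decimal, dA whole Å^2; JSON keeps
  full precision)
* ``interaction_map.tsv`` / ``interaction_map.json``
* ``contacts_per_frame.tsv`` - frame, residue pair, minimum distance, type
* ``ncc_per_frame.tsv``, ``sasa_per_frame.tsv``
* ``run.log`` - parameters, frame counts and per-chain formal charges
  (timestamp-free so repeated runs are byte-identical)

All analysis is deterministic: rerunning the same configuration on the
same inputs reproduces every report byte for byte.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import contacts as _contacts
from . import persistence as _persistence
from . import sasa as _sasa
from .contacts import ContactSeries, classify_pair, resolve_residue
from .persistence import PersistenceMap
from .ptm import PeptideSpec, compute_formal_charge, format_annotation
from .sasa import SasaSeries
from .trajectory import (
    Trajectory,
    heavy_atom_view,
    read_multimodel_pdb,
    read_topology,
)

__all__ = ["RunConfig", "ReportBundle", "PipelineError", "run_analysis", "compare_runs"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    traj_path: str
    topology_path: str
    outdir: str
    cutoff: float = 4.0
    threshold: float = 0.10
    probe: float = 1.4
    n_points: int = 960
    stride: int = 1
    label: str = ""
    conformation: str = ""
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("cutoff", "threshold", "probe"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.threshold > 1:
            raise ValueError("threshold must be in (0, 1]")
        if self.n_points < 32:
            raise ValueError("n_points must be >= 32")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


@dataclass
class ReportBundle:
    """In-memory results of one pipeline run."""

    label: str
    conformation: str
    n_frames: int
    mean_ncc: float
    delta_a: float
    interaction_map: PersistenceMap
    contact_series: ContactSeries
    sasa_series: SasaSeries
    charges: dict[str, int]

    @property
    def n_intermolecular(self) -> int:
        return _persistence.count_intermolecular(self.interaction_map)


@contextmanager
def _stage(name: str):
    try:
        yield
    except Exception as exc:
        raise PipelineError(f"pipeline stage {name!r} failed: {exc}") from exc


def _strided(traj: Trajectory, stride: int) -> Trajectory:
    if stride == 1:
        return traj
    from dataclasses import replace

    return replace(traj, frames=traj.frames[::stride])


def run_analysis(config: RunConfig) -> ReportBundle:
    """Execute the full analysis described by ``config`` and write reports."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger = logging.getLogger("ptmdimer.run")
    logger.setLevel(config.log_level.upper())
    logger.propagate = True
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        return _run(config, outdir, logger)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path, logger) -> ReportBundle:
    logger.info(
        "parameters: cutoff=%g A threshold=%g probe=%g A points=%d stride=%d",
        config.cutoff, config.threshold, config.probe, config.n_points,
        config.stride,
    )
    with _stage("read_topology"):
        topology = read_topology(config.topology_path)
    with _stage("read_trajectory"):
        traj = read_multimodel_pdb(config.traj_path, topology=topology)
    label = config.label or "/".join(
        topology[c].label or c for c in sorted(topology)
    )
    charges = {}
    for cid in sorted(topology):
        spec = topology[cid]
        charges[cid] = compute_formal_charge(spec)
        logger.info(
            "chain %s (%s, %s): formal charge %+d",
            cid, spec.label or "unlabelled", format_annotation(spec), charges[cid],
        )

    with _stage("heavy_atom_filter"):
        heavy = heavy_atom_view(traj)
    heavy = _strided(heavy, config.stride)
    logger.info(
        "analysing %d of %d frames (stride %d), %d heavy atoms per frame",
        len(heavy.frames), len(traj.frames), config.stride, heavy.n_atoms,
    )

    with _stage("contacts"):
        series = _contacts.compute_contact_series(
            heavy, cutoff=config.cutoff, include_intra=True
        )
        ncc = _contacts.mean_ncc(series)
    with _stage("persistence"):
        pmap = _persistence.build_interaction_map(
            series, topology, threshold=config.threshold
        )
    with _stage("sasa"):
        delta_a, sasa_series = _sasa.delta_sasa(
            heavy, probe=config.probe, n_points=config.n_points
        )

    bundle = ReportBundle(
        label=label,
        conformation=config.conformation,
        n_frames=series.n_frames,
        mean_ncc=ncc,
        delta_a=delta_a,
        interaction_map=pmap,
        contact_series=series,
        sasa_series=sasa_series,
        charges=charges,
    )
    with _stage("reports"):
        _write_reports(bundle, heavy, config, outdir)
    logger.info(
        "summary: N_cc=%.1f dA=%.0f A^2 n_intermolecular=%d",
        ncc, delta_a, bundle.n_intermolecular,
    )
    return bundle


def _write_reports(bundle: ReportBundle, heavy: Trajectory,
                   config: RunConfig, outdir: Path) -> None:
    with open(outdir / "summary.tsv", "w") as fh:
        fh.write("dimer\tconformation\tN_cc\tdelta_A\tn_intermolecular\n")
        fh.write(
            f"{bundle.label}\t{bundle.conformation}\t{bundle.mean_ncc:.1f}\t"
            f"{bundle.delta_a:.0f}\t{bundle.n_intermolecular}\n"
        )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(
            {
                "dimer": bundle.label,
                "conformation": bundle.conformation,
                "n_frames": bundle.n_frames,
                "N_cc": bundle.mean_ncc,
                "delta_A": bundle.delta_a,
                "n_intermolecular": bundle.n_intermolecular,
                "charges": bundle.charges,
                "cutoff": config.cutoff,
                "threshold": config.threshold,
                "probe": config.probe,
                "n_points": config.n_points,
                "stride": config.stride,
            },
            fh, indent=1, sort_keys=True,
        )
        fh.write("\n")

    bundle.interaction_map.to_tsv(outdir / "interaction_map.tsv")
    bundle.interaction_map.to_json(outdir / "interaction_map.json")

    topology = heavy.topology
    with open(outdir / "contacts_per_frame.tsv", "w") as fh:
        fh.write("frame\tchain_a_res\tchain_b_res\tmin_distance_A\tcategory\n")
        for f, frame in enumerate(heavy.frames):
            dists = _contacts.min_residue_distances(frame)
            for pair in sorted(dists):
                d = dists[pair]
                if d >= config.cutoff:
                    continue
                category = classify_pair(
                    resolve_residue(topology, pair[0]),
                    resolve_residue(topology, pair[1]),
                ).category
                fh.write(
                    f"{f + 1}\t{pair[0][0]}:{pair[0][1]}\t{pair[1][0]}:{pair[1][1]}"
                    f"\t{d:.3f}\t{category}\n"
                )

    with open(outdir / "ncc_per_frame.tsv", "w") as fh:
        fh.write("frame\tncc\n")
        for f, count in enumerate(bundle.contact_series.per_frame_ncc):
            fh.write(f"{f + 1}\t{count}\n")

    s = bundle.sasa_series
    with open(outdir / "sasa_per_frame.tsv", "w") as fh:
        fh.write("frame\tA1\tA2\tA12\tburied\n")
        for f in range(len(s)):
            fh.write(
                f"{f + 1}\t{s.a1[f]:.3f}\t{s.a2[f]:.3f}\t{s.a12[f]:.3f}\t"
                f"{s.buried[f]:.3f}\n"
            )


def compare_runs(bundles) -> pd.DataFrame:
    """Long-format comparison across runs, keyed by (dimer, conformation)."""
    bundles = list(bundles)
    if len(bundles) < 2:
        raise ValueError("compare_runs needs at least two bundles")
    keys = [(b.label, b.conformation) for b in bundles]
    dupes = {k for k in keys if keys.count(k) > 1}
    if dupes:
        raise ValueError(f"duplicate (dimer, conformation) keys: {sorted(dupes)}")
    rows = [
        {
            "dimer": b.label,
            "conformation": b.conformation,
            "N_cc": b.mean_ncc,
            "delta_A": b.delta_a,
            "n_intermolecular": b.n_intermolecular,
        }
        for b in bundles
    ]
    return pd.DataFrame(rows).set_index(["dimer", "conformation"]).sort_index()
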