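from fractions import Fraction

import numpy as np
import pytest

from ptmdimer.ptm import parse_annotation
from ptmdimer.synthetic import (
    AssociationSchedule,
    Episode,
    generate_dimer_trajectory,
)
from ptmdimer.trajectory import AtomRecord, Frame


def make_atom(name, element, xyz, chain="A", res_index=1, res_name="GLY"):
    return AtomRecord(
        atom_name=name,
        element=element,
        residue_index=res_index,
        residue_name=res_name,
        chain_id=chain,
        xyz=tuple(float(v) for v in xyz),
    )


def two_chain_frame(coords_a, coords_b, element="C"):
    """Frame with one single-atom residue per coordinate, chains A and B."""
    atoms = [
        make_atom(f"C{i+1}", element, xyz, chain="A", res_index=i + 1)
        for i, xyz in enumerate(coords_a)
    ] + [
        make_atom(f"C{i+1}", element, xyz, chain="B", res_index=i + 1)
        for i, xyz in enumerate(coords_b)
    ]
    return Frame(atoms=tuple(atoms))


def random_two_chain_frame(rng, n_a, n_b, box=12.0):
    return two_chain_frame(
        rng.uniform(-box, box, size=(n_a, 3)),
        rng.uniform(-box, box, size=(n_b, 3)),
    )


@pytest.fixture(scope="session")
def p1m2_spec():
    return parse_annotation("ART[ph]K[me3]QTAR[me2]KSTG-NME", label="P1M2")


@pytest.fixture(scope="session")
def p0m0_spec():
    return parse_annotation("ARTKQTARKSTG-NME", label="P0M0 (ala)")


@pytest.fixture(scope="session")
def small_dimer(p1m2_spec, p0m0_spec):
    """40-frame dimer with one pair in contact half the time (seeded)."""
    schedule = AssociationSchedule(
        episodes=(Episode(3, 8, Fraction(1, 2)),),
        n_frames=40,
        noise_sigma=0.2,
        seed=7,
    )
    return generate_dimer_trajectory(p1m2_spec, p0m0_spec, "extended", schedule)


@pytest.fixture(scope="session")
def apart_dimer(p1m2_spec, p0m0_spec):
    """20-frame dimer whose chains stay >= 20 A apart in every frame."""
    schedule = AssociationSchedule(
        episodes=(),
        n_frames=20,
        apart_distance=20.0,
        noise_sigma=0.2,
        seed=11,
    )
    return generate_dimer_trajectory(p1m2_spec, p0m0_spec, "helical", schedule)
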