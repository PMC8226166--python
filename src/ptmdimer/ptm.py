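"""Modified-peptide model: annotated sequences, PTM states and formal charge.

The histone H3 tail peptides studied here carry combinatorial
post-translational modifications (PTMs): phosphorylation of Ser/Thr,
mono/di/trimethylation of Lys, asymmetric dimethylation of Arg, and Lys
acetylation.  This module represents such peptides as explicit residue
lists with per-residue PTM states and terminal caps, and computes the
formal net charge at neutral pH from fixed per-group contributions:

* free N-terminal amine            +1   (acetyl cap ACE: 0)
* free C-terminal carboxylate      -1   (N-methyl amide cap NMe: 0)
* Arg guanidinium (any methylation) +1
* Lys ammonium (any methylation)   +1, acetyl-Lys 0
* Asp/Glu carboxylate              -1
* phospho-Ser/Thr/Tyr              -2   (fully deprotonated phosphate)
* His and everything else           0

Annotated-sequence grammar (the package's own syntax)::

    [ACE-]<one-letter code>([ph|me1|me2|me3|ac])* ... [-NME]

e.g. ``ACE-R[me2]T[ph]K[me3]QTAR[me2]K[me3]S[ph]TG-NME`` is the fully
modified, terminally capped H3(1-12) analogue with net charge 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable

__all__ = [
    "ResiduePTM",
    "PeptideSpec",
    "AnnotationError",
    "MalformedTagError",
    "IncompatiblePTMError",
    "EmptySequenceError",
    "parse_annotation",
    "format_annotation",
    "compute_formal_charge",
    "builtin_peptides",
    "load_peptide_table",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: PTM tag -> residues it may sit on.  me3/ac are lysine-only; arginine
#: supports mono- and (asymmetric) di-methylation.
_PTM_TARGETS = {
    "ph": set("STY"),
    "me1": set("KR"),
    "me2": set("KR"),
    "me3": set("K"),
    "ac": set("K"),
}

PTM_STATES = ("none", "ph", "me1", "me2", "me3", "ac")


class AnnotationError(ValueError):
    """Base class for annotated-sequence parse errors."""


class MalformedTagError(AnnotationError):
    """Unknown or syntactically invalid PTM tag / residue code."""


class IncompatiblePTMError(AnnotationError):
    """PTM tag placed on a residue that cannot chemically carry it."""


class EmptySequenceError(AnnotationError):
    """Annotation contains no residues."""


@dataclass(frozen=True)
class ResiduePTM:
    """One residue with its PTM state and 1-based position in the peptide."""

    base: str
    ptm: str = "none"
    position: int = 0

    def __post_init__(self) -> None:
        if self.base not in AMINO_ACIDS:
            raise MalformedTagError(
                f"position {self.position}: unknown residue code {self.base!r}"
            )
        if self.ptm not in PTM_STATES:
            raise MalformedTagError(
                f"position {self.position}: unknown PTM state {self.ptm!r}"
            )
        if self.ptm != "none" and self.base not in _PTM_TARGETS[self.ptm]:
            raise IncompatiblePTMError(
                f"position {self.position}: PTM {self.ptm!r} is not allowed "
                f"on residue {self.base!r}"
            )


@dataclass(frozen=True)
class PeptideSpec:
    """An annotated peptide: residues, terminal caps and a free-text label."""

    residues: tuple[ResiduePTM, ...]
    n_cap: str = "free_amine"  # or "ACE"
    c_cap: str = "free_acid"  # or "NMe"
    label: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise EmptySequenceError("peptide has no residues")
        if self.n_cap not in ("free_amine", "ACE"):
            raise ValueError(f"unknown N-cap {self.n_cap!r}")
        if self.c_cap not in ("free_acid", "NMe"):
            raise ValueError(f"unknown C-cap {self.c_cap!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.base for r in self.residues)

    def with_label(self, label: str) -> "PeptideSpec":
        return replace(self, label=label)


_TOKEN = re.compile(r"([A-Za-z])(\[([^\]]*)\])?")


def parse_annotation(text: str, label: str = "") -> PeptideSpec:
    """Parse an annotated-sequence string into a :class:`PeptideSpec`.

    Raises a subclass of :class:`AnnotationError` naming the offending
    position for malformed tags, chemically impossible PTM placements and
    empty sequences.
    """
    body = text.strip()
    n_cap = "free_amine"
    c_cap = "free_acid"
    if body.upper().startswith("ACE-"):
        n_cap = "ACE"
        body = body[4:]
    if body.upper().endswith("-NME"):
        c_cap = "NMe"
        body = body[:-4]
    if not body:
        raise EmptySequenceError(f"annotation {text!r} contains no residues")

    residues: list[ResiduePTM] = []
    pos = 0
    i = 0
    while i < len(body):
        m = _TOKEN.match(body, i)
        if m is None:
            raise MalformedTagError(
                f"position {pos + 1}: unexpected character {body[i]!r} "
                f"in annotation {text!r}"
            )
        pos += 1
        base = m.group(1).upper()
        tag = m.group(3)
        if tag is None:
            ptm = "none"
        else:
            ptm = tag.lower()
            if ptm not in _PTM_TARGETS:
                raise MalformedTagError(
                    f"position {pos}: unknown PTM tag {tag!r}"
                )
        residues.append(ResiduePTM(base=base, ptm=ptm, position=pos))
        i = m.end()
    return PeptideSpec(
        residues=tuple(residues), n_cap=n_cap, c_cap=c_cap, label=label
    )


def format_annotation(spec: PeptideSpec) -> str:
    """Inverse of :func:`parse_annotation` (caps and tags, no label)."""
    parts = []
    if spec.n_cap == "ACE":
        parts.append("ACE-")
    for res in spec.residues:
        parts.append(res.base)
        if res.ptm != "none":
            parts.append(f"[{res.ptm}]")
    if spec.c_cap == "NMe":
        parts.append("-NME")
    return "".join(parts)


def _side_chain_charge(res: ResiduePTM) -> int:
    if res.ptm == "ph":
        return -2
    if res.base == "R":
        return 1
    if res.base == "K":
        return 0 if res.ptm == "ac" else 1
    if res.base in "DE":
        return -1
    return 0


def compute_formal_charge(spec: PeptideSpec) -> int:
    """Formal net charge of the peptide, in elementary charge units.

    Sums the terminal contributions (+1 free amine, -1 free acid, 0 for
    either cap) and the fixed side-chain contributions listed in the module
    docstring.  Methylation of Lys/Arg never changes the charge; each
    phosphate contributes -2.
    """
    charge = 0
    if spec.n_cap == "free_amine":
        charge += 1
    if spec.c_cap == "free_acid":
        charge -= 1
    charge += sum(_side_chain_charge(r) for r in spec.residues)
    return charge


#: The four study peptides: label -> annotation.  P0M0 is the unmodified
#: H3(1-12) tail (ala: native Ala1; ace: Ala1 replaced by an acetyl cap),
#: P1M2 carries the mitotic phospho-T3/trimethyl-K4/dimethyl-R8 mark set,
#: and P2M4 is the fully modified, charge-neutral variant.
BUILTIN_ANNOTATIONS: tuple[tuple[str, str], ...] = (
    ("P0M0 (ala)", "ARTKQTARKSTG-NME"),
    ("P0M0 (ace)", "ACE-RTKQTARKSTG-NME"),
    ("P1M2", "ART[ph]K[me3]QTAR[me2]KSTG-NME"),
    ("P2M4", "ACE-R[me2]T[ph]K[me3]QTAR[me2]K[me3]S[ph]TG-NME"),
)


def builtin_peptides() -> list[PeptideSpec]:
    """The four bundled H3(1-12) study peptides (charges +5, +4, +3, 0)."""
    return [parse_annotation(ann, label=lab) for lab, ann in BUILTIN_ANNOTATIONS]


def load_peptide_table(path=None) -> list[PeptideSpec]:
    """Load peptides from a ``label<TAB>annotation`` text file.

    With no path, reads the bundled table of the four study peptides.
    """
    if path is None:
        source = resources.files("ptmdimer.data").joinpath("peptides.tsv")
        lines = source.read_text().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    specs = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, annotation = line.split("\t")
        specs.append(parse_annotation(annotation, label=label))
    return specs
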