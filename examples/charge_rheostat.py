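"""Formal charges of variably modified H3(1-12) tail peptides.

Parses the four bundled study peptides and a progressive-phosphorylation
series, printing the formal net charge of each.  Methylation leaves the
charge untouched while every phosphate removes two units, so multisite
phosphorylation walks the peptide from +5 down to the zero-charge state —
the charge "rheostat" that governs how strongly two tails associate.
"""

from ptmdimer import builtin_peptides, compute_formal_charge, format_annotation, parse_annotation

print("Bundled study peptides:")
for spec in builtin_peptides():
    print(f"  {spec.label:<11s} {format_annotation(spec):<50s} {compute_formal_charge(spec):+d}")

print("\nProgressive phosphorylation of the capped, methylated tail:")
series = [
    "ACE-R[me2]TK[me3]QTAR[me2]K[me3]STG-NME",
    "ACE-R[me2]T[ph]K[me3]QTAR[me2]K[me3]STG-NME",
    "ACE-R[me2]T[ph]K[me3]QTAR[me2]K[me3]S[ph]TG-NME",
]
for annotation in series:
    spec = parse_annotation(annotation)
    n_phos = sum(r.ptm == "ph" for r in spec.residues)
    print(f"  {n_phos} phosphate(s): charge {compute_formal_charge(spec):+d}")
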