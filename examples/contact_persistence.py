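"""Close contacts and interaction persistence on a synthetic dimer.

Builds a 200-frame synthetic trajectory of a PMM-modified (P1M2) and an
unmodified (P0M0) H3 tail in which the phospho-T3 / R8 pair touches in
64% of frames and R2 / T3 in 19%, then recovers both persistences, the
time-averaged close-contact count N_cc, and the typed interaction map.
"""

from fractions import Fraction

from ptmdimer import (
    AssociationSchedule,
    Episode,
    build_interaction_map,
    compute_contact_series,
    count_intermolecular,
    generate_dimer_trajectory,
    mean_ncc,
    parse_annotation,
)

spec_a = parse_annotation("ART[ph]K[me3]QTAR[me2]KSTG-NME", label="P1M2")
spec_b = parse_annotation("ARTKQTARKSTG-NME", label="P0M0 (ala)")

schedule = AssociationSchedule(
    episodes=(
        Episode(3, 8, Fraction(64, 100)),  # phospho-T3 (A) with R8 (B)
        Episode(2, 3, Fraction(19, 100)),  # R2 (A) with T3 (B)
    ),
    n_frames=200,
    seed=2024,
)
traj, truth = generate_dimer_trajectory(spec_a, spec_b, "extended", schedule)

series = compute_contact_series(traj)
pmap = build_interaction_map(series, traj.topology)

print(f"N_cc (mean inter-chain close contacts): {mean_ncc(series):.2f}")
print(f"intermolecular interactions above 10%: {count_intermolecular(pmap)}")
print("\npair            scope            persistence  type")
for e in pmap.intermolecular():
    pair = f"{e.pair[0][0]}:{e.pair[0][1]}-{e.pair[1][0]}:{e.pair[1][1]}"
    print(f"{pair:<15s} {e.scope:<16s} {e.percent:5.1f}%      {e.interaction.category}")
print("\nScheduled fractions were", {
    f"{p[0][0]}:{p[0][1]}-{p[1][0]}:{p[1][1]}": str(f)
    for p, f in truth.scheduled_fractions.items()
}, "- recovered exactly.")
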