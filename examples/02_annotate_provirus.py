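"""Structurally annotate one provirus: LTRs, PBS/tRNA, protein motifs.

Builds a synthetic provirus, ages it 15 My, and runs the annotation
scanners: terminal-repeat (LTR) discovery, primer-binding-site matching
against the tRNA library, zinc-finger / GPY/F motif scanning, base
composition and the pre-gag ORF.
"""

from ervkit import annotate, simulate

template = simulate.make_template(seed=1)
provirus = simulate.evolve(template.sequence(), age_my=15.0, seed=2)

ltr5, ltr3 = annotate.locate_ltrs(provirus)
print(f"5'LTR nt {ltr5.to_1based()[0]}-{ltr5.to_1based()[1]}, "
      f"3'LTR nt {ltr3.to_1based()[0]}-{ltr3.to_1based()[1]}")

library = simulate.load_pbs_library()
pbs = annotate.find_pbs(provirus, ltr5.end, library)
print(f"PBS: present={pbs.present} tRNA={pbs.best_trna} "
      f"identity={pbs.identity:.2f}")

presence = annotate.motif_presence(annotate.scan_motifs(provirus))
print("motifs intact:", presence)

comp = annotate.composition(provirus)
print(f"composition A={comp.a} C={comp.c} G={comp.g} T={comp.t} "
      f"purine bias={comp.purine_bias}")

iv = template.feature_intervals()
orf = annotate.find_pregag_orf(provirus[iv["pregag"][0] : iv["pregag"][1]])
print("pre-gag ORF:", f"nt {orf.start + 1}-{orf.end}" if orf else "none")
# After 15 My of neutral decay some motifs may already carry stops or
# anchor substitutions; presence flags report only intact copies, the
# way motif presence percentages are counted across a locus set.
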