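"""Pathway completeness, marker calls, and dsrAB-orientation gating for
nitrogen- and sulfur-cycle gene sets.

A pathway is an ordered list of steps; each step offers alternative gene
complexes whose subunits must all be present.  Denitrification, for
instance, is NO3->NO2 (napAB or narGHI), NO2->NO (nirS or nirK),
NO->N2O (norBC), N2O->N2 (nosZ).
"""

from flocprofiler import (
    SimilarityRecord,
    classify_dsrab,
    denitrifier_mode,
    marker_call,
    pathway_completeness,
    sox_rdsr_cooccurrence,
)
from flocprofiler.pathways import get_definition

genomes = {
    "aerobic_denitrifier": {"napA", "napB", "nirS", "norB", "norC", "nosZ"},
    "anaerobic_partial": {"narG", "narH", "narI", "nirK"},
    "dnra_genome": {"narG", "narH", "narI", "nirB", "nirD"},
    "sulfur_oxidizer": {"soxX", "soxA", "soxY", "soxZ", "soxB", "soxC", "soxD",
                        "dsrA", "dsrB"},
}

denitrification = get_definition("denitrification")
for name, genes in genomes.items():
    call = pathway_completeness(genes, denitrification, scope_id=name)
    print(f"{name:22} denitrification completeness {call.completeness_fraction:.2f} "
          f"(steps {sorted(call.satisfied_steps)}), mode={denitrifier_mode(genes)}, "
          f"nirS/nirK marker={marker_call(genes, 'denitrification')}, "
          f"nirBD marker={marker_call(genes, 'dnra')}")

# The sulfur oxidizer carries both the sox cluster and dsrAB; whether dsrAB
# counts as the reverse (oxidative) enzyme is decided by its nearest labelled
# reference in a similarity table.
hits = [
    SimilarityRecord("sulfur_oxidizer", "ref_ox", "oxidative", 88.2, 380),
    SimilarityRecord("sulfur_oxidizer", "ref_red", "reductive", 64.0, 380),
]
orientation = classify_dsrab(hits)
print("\ndsrAB orientation:", orientation)

sox_call = pathway_completeness(genomes["sulfur_oxidizer"], get_definition("sox"),
                                scope_id="sulfur_oxidizer")
rdsr_call = pathway_completeness(genomes["sulfur_oxidizer"], get_definition("rdsr"),
                                 scope_id="sulfur_oxidizer")
both = sox_rdsr_cooccurrence([sox_call, rdsr_call], orientation)
print("genomes with sox + oxidative rdsr:", sorted(both))
# With an 88% oxidative vs 64% reductive best hit the dsrAB is oxidative, so
# this genome is credited with both sox- and rdsr-mediated sulfur oxidation.
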