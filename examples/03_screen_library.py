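"""Screen a predicted scaffold against a compound library with the
fingerprint + multi-fragment-MCS + Bray-Curtis mixed score.

Run:  python examples/03_screen_library.py
"""

from scaffoldmine import fixtures, screening
from scaffoldmine.psm import count_psms

bundle = fixtures.generate_fixtures(seed=0)
db = screening.ingest({"fixture": bundle.library})
print(f"library: {len(db)} unique compounds")

query = bundle.true_product_smiles  # pretend this is our prediction
matches = screening.screen([query], count_psms(query), db, top_n=5)
print(f"\ntop 5 matches for {query}:")
print(f"{'rank':>4} {'compound':16s} {'sim':>5} {'mcs':>5} {'psm':>5} {'mixed':>6}")
for m in matches[:5]:
    print(
        f"{m.rank:4d} {m.compound_id:16s} {m.similarity_score:5.2f} "
        f"{m.mcs_score:5.2f} {m.psm_score:5.2f} {m.mixed_score:6.3f}"
    )
# The true product scores similarity 1.0 and MCS 1.0 and therefore ranks
# first; decoy peptides sharing residues trail with partial MCS scores.
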