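"""Normalize and alphabetize chemical shifts.

Builds a small synthetic corpus, learns the 120 per-(amino acid, atom)
min/max scale entries, and shows how one residue's six shifts become six
letters of the 11-letter feature alphabet.
"""

from shapestring import SynthConfig, alphabetize_record, fit_scale_table, generate

corpus = [rec for rec, _, _ in generate(SynthConfig(n_chains=30, seed=1))]
table = fit_scale_table(corpus)
print(f"scale table entries: {len(table)} (one min/max pair per aa x atom)")

rec = corpus[0]
letters = alphabetize_record(rec, table)
res = rec.residues[0]
print(f"\nchain {rec.chain_id}, residue 1 ({res.aa}):")
for atom, letter in zip(("HA", "H", "N", "CA", "CB", "C"), letters[0]):
    value = res.shifts[atom]
    shown = "vacant" if value is None else f"{value:7.2f} ppm"
    print(f"  {atom:>2}: {shown}  ->  letter {letter}")
print(
    "\nletters L..G are the ten equal bins of the rescaled [0,1] shift; "
    "N marks an unassigned cell."
)
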