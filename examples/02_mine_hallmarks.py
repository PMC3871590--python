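"""Mine hallmark patterns: short motifs with conserved shape letters.

On a synthetic annotated corpus, enumerates all 2-4 residue substrings
with enough occurrences and keeps those whose positions carry a shape
letter far more often than the corpus background (binomial upper tail).
"""

from shapestring import SynthConfig, generate, mine_patterns

corpus = [
    (rec.sequence, shape)
    for rec, shape, _ in generate(SynthConfig(n_chains=60, seed=2))
]
patterns = mine_patterns(corpus, min_support=20, max_p=0.001)
print(f"{len(patterns)} patterns with at least one conserved position\n")
print("pattern  support  conserved letters (p-value)")
for pat in sorted(patterns, key=lambda p: min(p.p_values))[:10]:
    cols = ", ".join(
        f"pos{j}:{letter} ({pat.p_values[j]:.1e})"
        for j, letter in enumerate(pat.conserved_letters())
        if letter is not None
    )
    print(f"{pat.pattern:<8} {pat.support:<8} {cols}")
print(
    "\na small p-value means that shape letter appears at that motif "
    "position far above its corpus-wide frequency."
)
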