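"""Multilingual concept entry: lay terms in five languages map to one CUI.

Loads the bundled mini concept table, resolves "heart attack" and its
German and Spanish equivalents to the same concept identifier, expands
the concept back into all indexed synonyms, and autosuggests from the
prefix "Hemophi".
"""

from studynet import expand_cui, paper_worked_examples, resolve_term, suggest

we = paper_worked_examples()

for term in ("heart attack", "Herzinfarkt", "ataque al corazón"):
    print(f"{term!r:28} -> {resolve_term(we.index, term)}")
# All three print the same single CUI: entering a lay or non-English term
# reaches the same medical concept, here myocardial infarction.

cui = resolve_term(we.index, "heart attack")[0]
print(f"\nsynonyms of {cui}:")
for rec in sorted(expand_cui(we.index, cui), key=lambda r: (r.language, r.term)):
    print(f"  [{rec.language}] {rec.term}  (MeSH {rec.mesh_descriptor})")

print("\nautosuggest 'Hemophi':")
for s in suggest(we.index, "Hemophi", limit=5):
    print(f"  {s.term}  ({s.cui}, preferred={s.preferred})")
# Both subtype concepts, Hemophilia A and B, surface from the shared prefix.
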