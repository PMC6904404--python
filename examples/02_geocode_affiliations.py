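"""The affiliation geocoding cascade: facility > city+country > population.

Resolves three unstructured affiliation strings against the bundled
gazetteer and trial-derived facility index, one per cascade priority.
"""

from studynet import geocode_affiliation, paper_worked_examples

we = paper_worked_examples()

cases = [
    # priority 1: "University of Leeds" is a facility known from the trial corpus
    "Institute of Cardiology, University of Leeds, Leeds LS184AB, United Kingdom",
    # priority 2: Springfield is ambiguous, but the country phrase decides
    "Dept. of Medicine, Springfield, United States",
    # priority 3: no country evidence -> the most populous Springfield wins
    "Laboratory of Medicine, Springfield",
]

for text in cases:
    res = geocode_affiliation(text, we.gazetteer, we.facility_index)
    print(f"{text}\n  -> {res.method.value:16} {res.matched_city} "
          f"({res.point.lat:.4f}, {res.point.lon:.4f}) "
          f"country={res.matched_entry.country}\n")
# The method field records which cascade step fired; the US Springfield
# (population 167,000) beats the Australian one (5,000) at priority 3.
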