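"""Filter ontology parameters by the three selection criteria.

A parameter enters the scoring model only when it is relevant (documented
link to welfare), practicable (measurable on-farm) and reliable. VSI and
hematocrit fail those criteria and drop out of the selection.
"""

from fishwelfare import default_ontology, degree, select_parameters

onto = default_ontology()
print(f"needs: {len(onto.needs)}, candidate parameters: {len(onto.parameters)}")
print(f"respiration links in the packaged excerpt: {degree(onto, 'respiration')}")

selected = select_parameters(onto, relevant=True, practicable=True, reliable=True)
print(f"parameters meeting all three criteria: {len(selected)} (the model registry)")
excluded = {p.id for p in onto.parameters} - {p.id for p in selected}
print(f"excluded: {sorted(excluded)}")
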