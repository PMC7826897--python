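"""Compare two assessments run under the same model configuration.

Farm 3 (outdoor flow-through, several problems) against farm 5 (large
indoor RAS, near-optimal): positive deltas mean the later assessment
grades better.
"""

from fishwelfare import build_report, compare_assessments, default_model_config, load_farm_fixture

cfg = default_model_config()
earlier = build_report(load_farm_fixture(3, cfg), cfg)
later = build_report(load_farm_fixture(5, cfg), cfg)
comp = compare_assessments(earlier, later)
for mid, delta in comp.deltas.items():
    print(f"module {mid:>2}: delta {delta:+.2f}")
print("parameters whose interval changed:", len(comp.changed_parameters))
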