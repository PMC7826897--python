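"""Grade one packaged farm visit with the default 80-parameter model.

Farm 3 is an extensive outdoor flow-through trout farm with documentation
gaps, low dissolved oxygen and visible gill damage; every module grade
prints with its semantic welfare category.
"""

from fishwelfare import build_report, default_model_config, format_report_table, load_farm_fixture

cfg = default_model_config()
assessment = load_farm_fixture(3, cfg)
report = build_report(assessment, cfg)
print(format_report_table(report))
print()
print("Lower grades point at the module causing the problem;")
print("categories: <0.25 critical, <0.5 poor, <0.75 acceptable, else good.")
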