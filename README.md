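# fishwelfare

Modular, config-driven welfare assessment for farmed fish.

Welfare on a fish farm cannot be read off a single instrument: it emerges
from farm management, water quality, the behaviour of the group, and the
external and internal condition of individual fish. `fishwelfare` implements
a complete assessment pipeline for aquaculture scientists, veterinarians and
farmers: an ontology of welfare **needs** linked to measurable **parameters**,
an 80-parameter scoring registry organised in those five **modules**
(M, W, FG, FE, FI), and an exponent-weighted grade equation that turns one
farm visit into five interpretable grades. Deliberately, the five grades are
never collapsed into one overall index — keeping them separate is what makes
the cause of a welfare problem visible.

## The model

Each measured parameter *i* falls into an interval carrying a discretised
parameter score `PS_i ∈ [-1, 0]` (0 = no or positive influence on welfare,
-1 = negative) and a score weight `SW_i ∈ {1..5}` for stressor severity;
the parameter itself carries an expert relevance weight `PW_i ∈ {1..5}`.
A module's grade is the offset weighted mean

```
MG = 1 + Σ_i PS_i · SW_i^SWE · PW_i^PWE  /  Σ_i SW_i^SWE · PW_i^PWE
```

over the parameters actually measured, so missing data drop out of the
numerator and denominator alike and partial assessments stay valid. The
exponents are SWE = PWE = 1.7 (calibrated on datasets with known welfare
impact; SWE = 0 for module M, whose intervals act on the fish only
indirectly). Grades live in [0, 1] and map to semantic categories:
[0, 0.25) critical, [0.25, 0.5) poor, [0.5, 0.75) acceptable, [0.75, 1] good.

Three parameters are calculated rather than measured: unionized ammonia
NH₃-N from TAN/pH/temperature via the freshwater equilibrium
`pKa = 0.09018 + 2729.92/T(K)`, relative dissolved oxygen against the
Benson–Krause solubility, and Fulton's condition factor
`K = 100·W/L³` (weight in g, *standard* length in cm).

## Worked example

Six real farm visits (indoor/outdoor, recirculating/flow-through, rainbow
trout/pikeperch) ship as fixtures. Grading the outdoor flow-through trout
farm (number 3 — documentation gaps, low dissolved oxygen, gill damage):

```python
from fishwelfare import build_report, default_model_config, format_report_table, load_farm_fixture

cfg = default_model_config()
report = build_report(load_farm_fixture(3, cfg), cfg)
print(format_report_table(report))
```

```
farm_id=3, location=outdoor, system=FTS, species=rainbow trout
module     grade  category
M           0.50  acceptable
W           0.52  acceptable
FG          0.62  acceptable
FE          0.66  acceptable
FI          0.63  acceptable
```

Every module sits in the lower "acceptable" band — this is the worst farm of
the six. Against the near-optimal indoor pikeperch RAS (farm 5), every
module improves (`examples/compare_visits.py` prints deltas of +0.47 for
management and +0.48 for water quality). The derived measures
(`examples/derived_water_chemistry.py`) show why single numbers matter: at
pH 7.5 and 11.5 °C only 0.0052 mg/L of a 0.79 mg/L TAN load is toxic NH₃-N,
and a 132 g trout of 19.5 cm standard length has Fulton K = 1.78 — an
overconditioned fish.

The same operations are available from a shell:

```
fishwelfare assess --assessment myfarm.csv            # grade a visit
fishwelfare derive --inputs water.csv                 # NH3-N, %O2, Fulton K
fishwelfare validate-config myconfig.yaml             # schema + invariants
fishwelfare export-ontology --format graphml          # needs/parameter graph
fishwelfare generate-fixture --seed 7 --out synth.csv # synthetic assessment
fishwelfare compare earlier.json later.json           # grade deltas
```

The shipped default configuration is a YAML document you can copy and edit:
interval boundaries, scores, weights and regulatory overrides are data, not
code, so the model adapts to other species, systems and jurisdictions
without touching the library.

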