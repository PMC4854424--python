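"""Qualitative expression calls from a planted matrix.

Generates genes with known expressed-tissue sets, developmental trends
across 18-42 days after flowering, and hormone/sugar responses, adds
log-scale noise, and prints the recovered calls next to the truth.
"""

from wrkycensus.expression import (
    ExpressionData,
    call_expressed,
    devel_trend,
    stage_series,
    treatment_response,
)
from wrkycensus.synthetic_data import gen_expression

gene_ids = [f"g{i:02d}" for i in range(8)]
values, meta, truth = gen_expression(gene_ids, noise_sd=0.1, seed=41)
data = ExpressionData(values, meta)

expressed = call_expressed(data)
trends = devel_trend(stage_series(data))
responses = treatment_response(data)

print(f"{'gene':<6}{'tissues (called)':<26}{'trend':<7}{'IAA@18d':<12}planted trend")
for gid in gene_ids:
    t = truth.expression[gid]
    tissues = ",".join(sorted(expressed[gid])) or "-"
    iaa = responses[gid].get(("IAA", 18), "-")
    print(f"{gid:<6}{tissues:<26}{trends[gid]:<7}{iaa:<12}{t.trend}")

print(
    "\n'up' means a monotone >=2-fold rise from Day18 to Day42; responses "
    "compare each treated fruit sample with its paired control at the same "
    "stage (>=2-fold either way)."
)
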