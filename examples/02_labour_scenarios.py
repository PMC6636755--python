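"""JHIFS labour add-on scenarios.

FFS/DPC tariffs embed routine ward labour, but the JHIFS (Gaihoren) hourly
tariffs price the staff time procedures actually consume.  Adding them —
with the 0.7 correction on day-of-procedure labour and uncorrected
pre-procedure labour — roughly doubles the MRgFUS saving under the 2018
rates, because unilateral DBS ties up more staff for longer.
"""

from tremorcma import reference_scenario, run_scenario
from tremorcma.report import render_table, round_jpy

for year in (2016, 2018):
    result = run_scenario(reference_scenario(mode="ffs", labour_year=year))
    print(f"\n=== FFS base case + {year} JHIFS labour ===")
    print(render_table(result, format="markdown"))
    print(f"saving incl. labour: JPY {-round_jpy(result.difference['grand_total']):,}")
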