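"""Rank therapies for one patient and render the decision-support report.

Loads the posterior archives written by 01_simulate_and_fit.py (run that
first), builds the per-DMT probabilities of staying relapse-free and
3mCDP-free over a chosen horizon, and prints the report with natural
frequencies ("N of 100 patients like you") and the per-predictor
contribution panel for the top-ranked therapy.
"""

from pathlib import Path

from dmtrank import PredictorVector, rank_therapies, render_report
from dmtrank.models import PosteriorFit

FITS = Path("scratch/example_fits")
relapse_fit = PosteriorFit.load(FITS / "relapse")
cdp_fit = PosteriorFit.load(FITS / "cdp")

# A 34-year-old woman, EDSS 2.5, two relapses in the last year, failing
# interferon after two years — a typical escalation decision.
patient = PredictorVector(
    age=34.0,
    sex="female",
    edss=2.5,
    current_dmt="interferon_beta",
    current_dmt_duration=24.0,
    n_previous_dmts=1,
    any_previous_second_line=False,
    time_since_diagnosis=48.0,
    relapses_last_12m=2,
    time_since_last_relapse=5.0,
)

# The patient dislikes infusions: natalizumab is shaded, not hidden — it
# keeps its probability so the cost of the preference stays visible.
table = rank_therapies(
    relapse_fit, cdp_fit, patient, horizon_months=48.0,
    preferences={"natalizumab": "prefers no infusion therapy"},
)
doc, text = render_report(table, patient, relapse_fit, cdp_fit)
print(text)

top = table.top("relapse-free")[0]
panel = doc["outcomes"]["relapse-free"]["explanation"]
print(f"drivers of the rank-1 therapy ({top}) prediction:")
for c in sorted(panel["contributions"], key=lambda c: -abs(c["contribution"]))[:5]:
    pct = f", {c['percentile']:.0f}th percentile" if c["percentile"] is not None else ""
    print(f"  {c['predictor']:<28} {c['contribution']:+.3f}{pct}")
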