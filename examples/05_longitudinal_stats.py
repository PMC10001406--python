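"""Spline mixed-model statistics on a simulated maturation study.

Generates co- and tri-culture devices recorded at DIV 7-21, computes the
percent of active channels per device and session, fits the group x B-spline
mixed model with a device random intercept, and reports Holm-adjusted
marginal-mean contrasts.
"""

import pandas as pd

from measpike import compute_active_channels, emm_contrasts_holm, fit_spline_lme, simulate_study

study = simulate_study("maturation", seed=1)
rows = [
    dict(device=s.device, session=s.session, culture=s.culture,
         percent_active=compute_active_channels(s.truth.trains())[1])
    for s in study.sessions
]
table = pd.DataFrame(rows)
print(table.groupby(["culture", "session"])["percent_active"].mean().round(1))

fit = fit_spline_lme(table, "percent_active")
contrasts = emm_contrasts_holm(fit)
vs_base = contrasts[contrasts.comparison == "vs-baseline"]
print("\nvs-DIV-7 contrasts (Holm-adjusted):")
print(vs_base[["contrast", "estimate", "se", "p_adj"]].to_string(index=False))
# both cultures show a strongly significant rise in active channels by
# DIV 21; between-culture contrasts (not shown) stay null, since the two
# arms share the same configured trajectory.
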