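"""Temporal analyses on the packaged study tables: chi-square test of
between-year change in success, Kendall's W concordance of river rankings,
Levene's test of rate stability, and the exceedance mixed model.
"""

import numpy as np

import smoltrak as st

t2 = st.load_migration_summaries()
t1 = st.load_cohort_summaries()
multi = t2.groupby("river").filter(lambda g: len(g) > 1)

m = multi.merge(t1[["river", "year", "n_tagged"]], on=["river", "year"])
m = m[m["river"] != "Gryffe"]  # release-fallback year; excluded from the comparison
m = m.assign(n_entered=m["n_tagged"],
             n_succeeded=(m["migration_success"] * m["n_tagged"]).round().astype(int))
stat, df, p = st.temporal_chisq(m)
print(f"temporal chi-square: stat={stat:.1f}, df={df}, p={p:.2g}")

W, pw = st.kendalls_w(multi.pivot(index="river", columns="year", values="migration_success"))
print(f"Kendall's W (year-to-year concordance of river rankings): W={W:.2f}, p={pw:.2f}")

F, df1, df2, pl = st.levene_rate_variance(multi["rate_per_km"], multi["river"])
print(f"Levene rate-stability test: F({df1},{df2})={F:.2f}, p={pl:.2g}")

# does standardized discharge predict the rate? (synthetic null exceedances)
rng = np.random.default_rng(0)
data = multi.assign(exceedance=rng.uniform(20, 80, len(multi)))
fit, test = st.fit_rate_exceedance(data)
print(f"exceedance beta GLMM: coef={fit.params['exceedance']:.4f}, "
      f"LRT stat={test.statistic:.2f}, p={test.p:.2f}")
print("\nLarge chi-square + low W: success varies between years, and which")
print("rivers do well is not consistent from year to year.")
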