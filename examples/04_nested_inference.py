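"""Nested inference: test the group difference respecting the hierarchy.

Four spectra per mouse are not independent observations; the nested t-test
compares groups against between-mouse variation.  Also correlates each
exercised mouse's mean LDF score with the distance it ran.
"""

import ramanmuscle as rm

cohort, _ = rm.generate_cohort(rm.default_config(seed=1), ["unexercised", "exercised"])
matrix = rm.preprocess_cohort(cohort)
_, model = rm.fit_pipeline(matrix)

res = rm.nested_ttest(model.scores, matrix.subject_ids, matrix.group_labels)
print(f"nested t-test: F(1, {res.df_within}) = {res.f_statistic:.1f}, "
      f"p = {res.p_value:.3g}")
print(f"intraclass correlation of spectra within mouse: {res.icc:.3f} "
      "(high ICC = the 4 spectra of a mouse agree; the nested test is essential)")

ex = matrix.group_labels == "exercised"
corr = rm.correlate_covariate(
    model.scores[ex],
    matrix.subject_ids[ex],
    {m.subject_id: m.covariate for m in matrix.meta if m.group == "exercised"},
)
print(f"mean LDF score vs distance run: r = {corr.r:.3f} "
      f"(r^2 = {corr.r2:.2f}), p = {corr.p_value:.3g}, "
      f"slope = {corr.slope:.3f} score units per km")
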