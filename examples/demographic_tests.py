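"""Group-comparison statistics on demographic contingency tables.

The sample-description stage compares transitioned and non-transitioned
subjects on sex (chi-square, or Fisher's exact test when a cell is
sparse) and age (Mann-Whitney U / t-test). The tables below are male/
female counts per group; the p-values printed are the quantities used to
accept or reject a matched subsample.
"""

from armsml import stats

# sex (male/female) in a 21 T vs 54 NT cohort
res = stats.chi_square_2x2([[14, 7], [30, 24]])
print(f"chi-square: statistic {res.statistic:.3f}, p = {res.p_value:.3f}")
# p = 0.380: the sex split does not differ between groups

# a sparse protocol-specific table (one cell below 5) -> Fisher's exact
res = stats.fisher_exact_2x2([[2, 1], [14, 2]])
print(f"Fisher exact: p = {res.p_value:.3f}")
# p = 0.422: again no evidence of imbalance

# age matching criterion: two-sided Mann-Whitney U
ages_t = [22.1, 24.5, 19.8, 27.0, 23.3, 21.9]
ages_nt = [23.0, 22.8, 25.1, 20.5, 24.0, 22.2]
res = stats.mann_whitney_u(ages_t, ages_nt)
print(f"Mann-Whitney U = {res.statistic:.0f}, p = {res.p_value:.3f}")
# p > 0.05 would let this draw pass the age-matching criterion
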