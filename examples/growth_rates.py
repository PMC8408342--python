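"""Endpoint growth statistics: percent change and annualized compound rate.

Uses the published low-income-group aggregate levels for 2000 and 2015.
"""

from healthfin import annualized_growth, percent_change, round_half_away

gdp = (2_147_099.1, 5_352_788.9)      # millions, constant 2010 US$
gghed = (21_479.8, 63_651.65)

for label, pair in (("GDP", gdp), ("GGHE-D", gghed)):
    total = percent_change(*pair)
    annual = annualized_growth(*pair, 2000, 2015)
    print(f"{label:7s} total change {round_half_away(total, 1):7.1f}%   "
          f"annualized {round_half_away(annual, 1):4.1f}%/yr")

# The annualized rate compounds back to the total: (1 + 0.063)^15 ≈ 2.49,
# the ratio of the GDP endpoints. GGHE-D outgrowing GDP (7.5% vs 6.3%/yr)
# is what a rising GGHE-D/GDP share looks like in growth-rate terms.
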