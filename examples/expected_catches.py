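"""Expected seasonal catches of the simulated trapping design.

Prints the expected total catch per treatment and 20-day interval for the
field-data parameters (mean 1.47 individuals/trap/season, treatments 1x/2x/4x,
seasonal activity 25/49/13/9/4 %), before any random variation.  These are the
design-table values of the study: each column sums to the treatment's season
total (29.4, 58.8, 117.6 individuals over 20 traps).
"""

import trapbias as tb

params = tb.PARAMETER_SETS["field"]
table = tb.expected_table(params)
print(table.round(1).to_string())
print(
    "\nEach cell is mean_catch x multiplier x 20 traps x interval share;"
    "\nthe 'total' row gives the expected season catch per treatment."
)
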