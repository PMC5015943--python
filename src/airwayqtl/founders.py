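"""The eight Collaborative Cross founder strains.

Five classical inbred strains and three wild-derived strains. The fixed
order below is used consistently as the column order of every founder
dosage matrix in the package.
"""

FOUNDERS: tuple[str, ...] = (
    "A/J",
    "C57BL/6J",
    "129S1/SvImJ",
    "NOD/ShiLtJ",
    "NZO/HlLtJ",
    "CAST/EiJ",
    "PWK/PhJ",
    "WSB/EiJ",
)

N_FOUNDERS = len(FOUNDERS)

#: column names used in dosage CSV files (slashes are awkward in headers)
FOUNDER_COLUMNS: tuple[str, ...] = tuple(
    f.replace("/", "_") for f in FOUNDERS
)
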