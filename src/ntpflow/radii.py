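"""Van der Waals radius tables.

The Bondi (1964) set is the default for all clearance and contact
calculations; individual elements can be overridden through the
``radius_table`` argument of :func:`ntpflow.structures.read_structure`.
"""

from __future__ import annotations

#: Bondi van der Waals radii in Angstrom, keyed by element symbol.
BONDI: dict[str, float] = {
    "H": 1.20,
    "HE": 1.40,
    "LI": 1.82,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "NE": 1.54,
    "NA": 2.27,
    "MG": 1.73,
    "SI": 2.10,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "AR": 1.88,
    "K": 2.75,
    "NI": 1.63,
    "CU": 1.40,
    "ZN": 1.39,
    "GA": 1.87,
    "AS": 1.85,
    "SE": 1.90,
    "BR": 1.85,
    "KR": 2.02,
    "PD": 1.63,
    "AG": 1.72,
    "CD": 1.58,
    "IN": 1.93,
    "SN": 2.17,
    "TE": 2.06,
    "I": 1.98,
    "XE": 2.16,
    "PT": 1.75,
    "AU": 1.66,
    "HG": 1.55,
    "TL": 1.96,
    "PB": 2.02,
    "U": 1.86,
}

#: Radius assigned to elements absent from the table (with a warning).
DEFAULT_RADIUS: float = 1.5


def lookup_radius(element: str, table: dict[str, float] | None = None) -> float | None:
    """Return the vdW radius for ``element`` or ``None`` if unknown.

    Lookup is case-insensitive; ``table`` defaults to :data:`BONDI`.
    """
    tab = BONDI if table is None else table
    key = element.strip().upper()
    if key in tab:
        return tab[key]
    # allow caller tables keyed in mixed case
    for k, v in tab.items():
        if k.upper() == key:
            return v
    return None
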