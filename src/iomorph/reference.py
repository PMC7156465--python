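"""Bundled reference measurements from a five-forearm cadaveric study of
the interosseous membrane.

These are the published per-specimen tensile results (initial CSA, first
fibre-failure peak, ultimate force, stiffness, ultimate strain) plus the
optically measured DOB attachment widths and CCD-laser thickness, used to
cross-check the summary statistics and the trapezoid CSA model.  The DOB
was present in only one of the five specimens, so its rows carry a single
value.

Units: CSA mm^2, forces N, stiffness N/mm, strain %, widths/thickness mm.
"""

from __future__ import annotations

# Per-specimen tensile results, ordered by forearm number.
CADAVER_TENSILE: dict[str, list[dict[str, float]]] = {
    "CB": [
        {"specimen": "forearm1", "csa": 130.00, "first_peak": 68.81, "ultimate": 198.77, "stiffness": 33.09, "ultimate_strain": 3.36},
        {"specimen": "forearm2", "csa": 149.32, "first_peak": 132.60, "ultimate": 196.57, "stiffness": 27.71, "ultimate_strain": 3.80},
        {"specimen": "forearm3", "csa": 105.11, "first_peak": 136.80, "ultimate": 188.59, "stiffness": 43.48, "ultimate_strain": 3.43},
        {"specimen": "forearm4", "csa": 134.65, "first_peak": 90.09, "ultimate": 186.90, "stiffness": 34.02, "ultimate_strain": 6.15},
        {"specimen": "forearm5", "csa": 161.87, "first_peak": 210.70, "ultimate": 268.80, "stiffness": 79.33, "ultimate_strain": 5.20},
    ],
    "AB": [
        {"specimen": "forearm1", "csa": 53.05, "first_peak": 156.20, "ultimate": 156.20, "stiffness": 54.82, "ultimate_strain": 1.90},
        {"specimen": "forearm2", "csa": 45.34, "first_peak": 52.61, "ultimate": 87.59, "stiffness": 29.88, "ultimate_strain": 3.93},
        {"specimen": "forearm3", "csa": 94.81, "first_peak": 49.20, "ultimate": 49.20, "stiffness": 22.17, "ultimate_strain": 1.60},
        {"specimen": "forearm4", "csa": 40.50, "first_peak": 110.20, "ultimate": 128.80, "stiffness": 60.38, "ultimate_strain": 2.06},
        {"specimen": "forearm5", "csa": 68.68, "first_peak": 84.75, "ultimate": 87.07, "stiffness": 42.89, "ultimate_strain": 1.84},
    ],
    "DOAC": [
        {"specimen": "forearm1", "csa": 38.90, "first_peak": 279.60, "ultimate": 327.70, "stiffness": 83.93, "ultimate_strain": 2.36},
        {"specimen": "forearm2", "csa": 46.70, "first_peak": 38.58, "ultimate": 46.06, "stiffness": 30.32, "ultimate_strain": 1.33},
        {"specimen": "forearm3", "csa": 34.10, "first_peak": 242.40, "ultimate": 259.40, "stiffness": 154.40, "ultimate_strain": 1.54},
        {"specimen": "forearm4", "csa": 21.50, "first_peak": 74.04, "ultimate": 80.96, "stiffness": 40.04, "ultimate_strain": 1.43},
    ],
    "DOB": [
        {"specimen": "forearm5", "csa": 50.50, "first_peak": 63.40, "ultimate": 69.40, "stiffness": 23.57, "ultimate_strain": 1.43},
    ],
}

#: Optically measured (digital micrometre) DOB attachment widths, mm.
DOB_WIDTH_RADIAL_EXVIVO = 18.3
DOB_WIDTH_ULNAR_EXVIVO = 28.2

#: CCD-laser mean thickness of the DOB, mm.
DOB_THICKNESS_CCD = 2.17

#: Published DOB initial CSA, mm^2 (derived from the ex-vivo widths and
#: CCD thickness via the trapezoid model).
DOB_CSA_PUBLISHED = 50.50


def tensile_values(ligament_id: str, quantity: str) -> list[float]:
    """Per-specimen values of one tensile quantity for one ligament."""
    return [row[quantity] for row in CADAVER_TENSILE[ligament_id]]
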