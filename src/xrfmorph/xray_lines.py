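"""Characteristic X-ray emission line energies.

A small bundled table of Ka1 / Kb1 / La1 line energies (keV) for the elements
relevant to sedimentary fossil material in the 1.7-18.3 keV window: the major
matrix elements (P, K, Ca, Fe), the substituting traces of calcitic and
ferruginous carbonates (Sr, Mn, Zn, Ga, As, Rb, Y, ...) and a few rare-earth /
actinide L-lines (Ce, Nd, Th, U).  Energies marked ``tabulated`` follow
standard X-ray data tables (Deslattes et al. / X-ray data booklet values,
rounded to the eV); the detector resolution of an SDD (>120 eV FWHM at Mn Ka1)
makes finer precision irrelevant here.

Silicon drift detectors additionally produce *escape peaks* at
``E_line - 1.742 keV`` (the Si Ka energy lost when a fluoresced Si photon
escapes the sensor).
"""

from __future__ import annotations

import pandas as pd

#: Energy (keV) removed from a photon when a Si Ka photon escapes the detector.
SI_ESCAPE_KEV = 1.742

# (element, line, energy_keV, provenance)
_LINES: list[tuple[str, str, float, str]] = [
    ("P", "Ka1", 2.014, "tabulated"),
    ("P", "Kb1", 2.139, "tabulated"),
    ("K", "Ka1", 3.314, "tabulated"),
    ("K", "Kb1", 3.590, "tabulated"),
    ("Ca", "Ka1", 3.692, "printed"),
    ("Ca", "Kb1", 4.012, "tabulated"),
    ("Ti", "Ka1", 4.511, "tabulated"),
    ("Ti", "Kb1", 4.932, "tabulated"),
    ("V", "Ka1", 4.952, "tabulated"),
    ("V", "Kb1", 5.427, "tabulated"),
    ("Cr", "Ka1", 5.415, "tabulated"),
    ("Cr", "Kb1", 5.947, "tabulated"),
    ("Mn", "Ka1", 5.899, "tabulated"),
    ("Mn", "Kb1", 6.490, "tabulated"),
    ("Fe", "Ka1", 6.405, "printed"),
    ("Fe", "Kb1", 7.058, "tabulated"),
    ("Co", "Ka1", 6.930, "tabulated"),
    ("Co", "Kb1", 7.649, "tabulated"),
    ("Ni", "Ka1", 7.478, "tabulated"),
    ("Ni", "Kb1", 8.265, "tabulated"),
    ("Cu", "Ka1", 8.048, "tabulated"),
    ("Cu", "Kb1", 8.905, "tabulated"),
    ("Zn", "Ka1", 8.639, "tabulated"),
    ("Zn", "Kb1", 9.572, "tabulated"),
    ("Ga", "Ka1", 9.252, "tabulated"),
    ("Ga", "Kb1", 10.264, "tabulated"),
    ("Ge", "Ka1", 9.886, "tabulated"),
    ("Ge", "Kb1", 10.982, "tabulated"),
    ("As", "Ka1", 10.544, "tabulated"),
    ("As", "Kb1", 11.726, "tabulated"),
    ("Se", "Ka1", 11.222, "tabulated"),
    ("Se", "Kb1", 12.496, "tabulated"),
    ("Br", "Ka1", 11.924, "tabulated"),
    ("Br", "Kb1", 13.292, "tabulated"),
    ("Kr", "Ka1", 12.651, "tabulated"),
    ("Kr", "Kb1", 14.112, "tabulated"),
    ("Rb", "Ka1", 13.395, "tabulated"),
    ("Rb", "Kb1", 14.961, "tabulated"),
    ("Sr", "Ka1", 14.165, "tabulated"),
    ("Sr", "Kb1", 15.835, "tabulated"),
    ("Y", "Ka1", 14.958, "printed"),
    ("Y", "Kb1", 16.738, "tabulated"),
    ("Ce", "La1", 4.840, "tabulated"),
    ("Nd", "La1", 5.230, "tabulated"),
    ("Th", "La1", 12.969, "tabulated"),
    ("U", "La1", 13.615, "tabulated"),
]


def emission_lines() -> pd.DataFrame:
    """Return the bundled emission line table.

    Columns: ``element``, ``line``, ``energy_kev``, ``provenance``.
    (element, line) pairs are unique and energies strictly positive.
    """
    df = pd.DataFrame(_LINES, columns=["element", "line", "energy_kev", "provenance"])
    return df


def line_energy(element: str, line: str = "Ka1") -> float:
    """Energy (keV) of one line; KeyError if the table has no such entry."""
    for el, ln, e, _ in _LINES:
        if el == element and ln == line:
            return e
    raise KeyError(f"no tabulated line {line} for element {element}")
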