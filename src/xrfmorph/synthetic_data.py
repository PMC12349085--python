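"""Synthetic micro-XRF spectrum and dataset generator.

Generates labelled per-zone mean spectra with the statistical structure the
analysis pipeline assumes, so every stage is testable without real beamline
data.  The physical model, per channel of a 0.2-20.6 keV energy axis:

``lambda(E) = [background(E) + sum_e c_e sum_lines r_line N(E; E_line, sigma(E_line))
              + escape peaks + scatter feature] * sensitivity_session(E) * exposure
              + offset_session(E) * exposure``

with ``sigma(E) = FWHM(E)/2.355``, ``FWHM(E) = a + b sqrt(E)`` (silicon drift
detector energy resolution), Si escape peaks at ``E_line - 1.742 keV``, no
emission lines above the 18 keV excitation energy, and Poisson counting noise
on the final expectation.

The default scenario emulates the study design: 38 fossil specimens from 8
high-level clades across 7 sites, 6 analysed zones each (3 fossil, 3
sediment), 2 control specimens measured in all 3 acquisition sessions
(252 spectra in total).  Sediments sit on a calcitic (Ca/Sr-rich) to
ferruginous (Fe with correlated Zn/Ga/As/Rb/Y) composition gradient; fossil
zones blend the clade's elemental profile with the local sediment (thin or
poorly preserved fossils blend more); sessions differ by additive offset
curves, smooth sensitivity curves and a +-0.025 keV energy-axis jitter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .spectra import Spectrum, validate_manifest, write_spectrum
from .xray_lines import SI_ESCAPE_KEV, emission_lines

CHANNEL_LO = 0.2
CHANNEL_HI = 20.6
CHANNEL_STEP = 0.01
EXCITATION_KEV = 18.0

_CHANNELS = np.round(np.arange(CHANNEL_LO, CHANNEL_HI + CHANNEL_STEP / 2, CHANNEL_STEP), 6)

REFERENCE_SESSION = "DiffAbs-2018"
SESSIONS = ("DiffAbs-2018", "PUMA-2021", "PUMA-2024")

#: Trace elements held at the same concentration in every class (sediment and
#: all clades): they must never drive the discrimination.
CONSTANT_TRACE = {
    "Cr": 8.0, "Cu": 8.0, "Ge": 3.0, "Se": 4.0, "Br": 4.0, "Kr": 2.0,
}


@dataclass(frozen=True)
class DetectorModel:
    """SDD response: FWHM(E) = fwhm_a + fwhm_b sqrt(E) (keV), Si escape, Kb/Ka ratio."""

    fwhm_a: float = 0.05
    fwhm_b: float = 0.033
    escape_fraction: float = 0.02
    kbeta_ratio: float = 0.135

    def sigma(self, energy_kev: np.ndarray | float) -> np.ndarray | float:
        return (self.fwhm_a + self.fwhm_b * np.sqrt(energy_kev)) / 2.355


@dataclass(frozen=True)
class SessionEffect:
    """Setup-specific distortions of one acquisition session."""

    name: str
    scatter_amp: float = 3.0       # counts: elastic/inelastic scatter bump near 17.8 keV
    offset_amp: float = 0.0        # counts: additive low-energy offset, decays with E
    sens_slope: float = 0.0        # fractional sensitivity tilt across the energy range
    sens_bump_amp: float = 0.0     # localised sensitivity bump
    sens_bump_center: float = 10.0
    jitter_kev: float = 0.025      # energy-axis registration jitter (+- keV)

    def sensitivity(self, energy: np.ndarray) -> np.ndarray:
        s = 1.0 + self.sens_slope * (energy - 10.0) / 8.0
        s = s + self.sens_bump_amp * np.exp(-(((energy - self.sens_bump_center) / 1.5) ** 2))
        return np.clip(s, 0.2, None)

    def offset(self, energy: np.ndarray) -> np.ndarray:
        off = self.offset_amp * np.exp(-energy / 6.0)
        off = off + self.scatter_amp * np.exp(-(((energy - 17.8) / 0.45) ** 2))
        return off


@dataclass(frozen=True)
class SpecimenDesign:
    specimen_id: str
    clade: str
    site: str
    mineralogy: str
    poorly_preserved: bool = False
    control: bool = False


@dataclass(frozen=True)
class SimulationScenario:
    clade_profiles: Mapping[str, Mapping[str, float]]
    clade_blend: Mapping[str, float]
    design: tuple[SpecimenDesign, ...]
    sessions: tuple[SessionEffect, ...]
    detector: DetectorModel
    seed: int
    exposure: float = 80.0
    between_specimen_cv: float = 0.18
    within_specimen_cv: float = 0.08
    site_cv: float = 0.05
    poorly_preserved_blend: float = 0.85
    background_amp: float = 6.0
    background_tau: float = 5.0
    background_const: float = 0.4
    #: When set, only these elements keep their class-dependent design values;
    #: every other element is flattened to its across-class design mean in all
    #: compositions (controlled-recovery experiments with a known differing set).
    flatten_except: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a scenario seed is mandatory")
        for clade, profile in self.clade_profiles.items():
            for el, c in profile.items():
                if c < 0:
                    raise ValueError(f"negative concentration for {el} in clade {clade}")
        for clade, b in self.clade_blend.items():
            if not (0.0 <= b <= 1.0):
                raise ValueError(f"blend fraction for {clade} outside [0, 1]")
        if not (0.0 <= self.poorly_preserved_blend <= 1.0):
            raise ValueError("poorly_preserved_blend outside [0, 1]")


@dataclass
class SyntheticDataset:
    spectra: list[Spectrum]
    manifest: pd.DataFrame
    truth: pd.DataFrame


def sediment_composition(g: float) -> dict[str, float]:
    """Sediment elemental profile at gradient position g in [0, 1].

    g = 0: calcitic pole (Ca and substituting Sr high); g = 1: ferruginous
    pole (Fe high, with correlated Zn, Ga, As, Rb and Y enrichment).
    """
    g = float(np.clip(g, 0.0, 1.0))
    comp = {
        "Ca": 60.0 + 420.0 * (1.0 - g),
        "Sr": 3.0 + 20.0 * (1.0 - g),
        "Fe": 40.0 + 340.0 * g,
        "Zn": 4.0 + 22.0 * g,
        "Ga": 3.0 + 25.0 * g,
        "As": 3.0 + 28.0 * g,
        "Rb": 3.0 + 16.0 * g,
        "Y": 4.0 + 14.0 * g,
        "Mn": 12.0 + 18.0 * g,
        "K": 35.0,
        "Ti": 22.0,
        "P": 12.0,
        "Ni": 6.0,
        "Co": 4.0,
        "V": 6.0,
        "Ce": 5.0,
        "Nd": 4.0,
        "Th": 3.0,
    }
    comp.update(CONSTANT_TRACE)
    return comp


# Clade mean concentration profiles (arbitrary fluorescence-yield-scaled
# units).  Echinoderms are Ca/Sr-rich (calcitic skeletons); the phosphatic
# clades share a strong P signal but differ in their trace-element mixes
# (transition metals, REE and Th as apatite substituents); ammonoids are
# mixed carbonate.
_CLADE_PROFILES: dict[str, dict[str, float]] = {
    "echinoderm":      {"Ca": 620, "Sr": 38, "Mn": 26, "Fe": 18, "P": 10, "K": 8, "Ti": 2, "Zn": 4, "Rb": 2, "Y": 5, "Ga": 1, "As": 1,
                        "Ni": 4, "Co": 2, "V": 3, "Ce": 2, "Nd": 2, "Th": 1.5},
    "ammonoid":        {"Ca": 460, "Sr": 24, "Mn": 12, "Fe": 45, "P": 35, "K": 18, "Ti": 8, "Zn": 12, "Rb": 5, "Y": 8, "Ga": 1.5, "As": 1.5,
                        "Ni": 7, "Co": 4, "V": 5, "Ce": 4, "Nd": 3, "Th": 3},
    "arthropod":       {"Ca": 340, "Sr": 8, "Mn": 10, "Fe": 60, "P": 300, "K": 30, "Ti": 6, "Zn": 30, "Rb": 3, "Y": 18, "Ga": 1, "As": 1.5,
                        "Ni": 14, "Co": 5, "V": 6, "Ce": 4, "Nd": 3, "Th": 2.5},
    "brachiopod":      {"Ca": 320, "Sr": 10, "Mn": 20, "Fe": 50, "P": 340, "K": 15, "Ti": 18, "Zn": 8, "Rb": 2.5, "Y": 26, "Ga": 1, "As": 1,
                        "Ni": 6, "Co": 4, "V": 7, "Ce": 10, "Nd": 9, "Th": 8},
    "sponge":          {"Ca": 280, "Sr": 6, "Mn": 14, "Fe": 90, "P": 250, "K": 45, "Ti": 30, "Zn": 15, "Rb": 8, "Y": 10, "Ga": 2, "As": 2,
                        "Ni": 4, "Co": 3, "V": 9, "Ce": 12, "Nd": 7, "Th": 4},
    "actinopterygian": {"Ca": 380, "Sr": 16, "Mn": 7, "Fe": 45, "P": 320, "K": 20, "Ti": 4, "Zn": 46, "Rb": 2, "Y": 30, "Ga": 1, "As": 1,
                        "Ni": 6, "Co": 10, "V": 4, "Ce": 5, "Nd": 4, "Th": 2},
    "coleoid":         {"Ca": 300, "Sr": 9, "Mn": 34, "Fe": 70, "P": 210, "K": 60, "Ti": 12, "Zn": 20, "Rb": 14, "Y": 12, "Ga": 1.5, "As": 1.5,
                        "Ni": 8, "Co": 5, "V": 6, "Ce": 4, "Nd": 3, "Th": 3},
    "sarcopterygian":  {"Ca": 360, "Sr": 13, "Mn": 15, "Fe": 55, "P": 330, "K": 25, "Ti": 5, "Zn": 36, "Rb": 2.5, "Y": 16, "Ga": 1, "As": 1,
                        "Ni": 7, "Co": 7, "V": 5, "Ce": 5, "Nd": 4, "Th": 2.5},
}

#: Fossil/sediment signal blending per clade (probed depth exceeds thin
#: fossils, mixing sediment signal into fossil zones).
_CLADE_BLEND: dict[str, float] = {
    "echinoderm": 0.15,
    "ammonoid": 0.25,
    "arthropod": 0.30,
    "brachiopod": 0.30,
    "sponge": 0.50,
    "actinopterygian": 0.30,
    "coleoid": 0.35,
    "sarcopterygian": 0.30,
}


def _study_design() -> tuple[SpecimenDesign, ...]:
    """The 38-specimen design: clade x site layout of the studied assemblage."""
    spec: list[tuple[str, str, str, bool]] = []
    # (clade, site, mineralogy, poorly_preserved)
    spec += [("actinopterygian", "Paris Canyon", "phosphatic", False)]
    spec += [("sponge", "Paris Canyon", "phosphatic", False)] * 2
    spec += [("coleoid", "Paris Canyon", "phosphatic", False)]
    spec += [("ammonoid", "Paris Canyon", "calcitic", False)]
    spec += [("ammonoid", "Paris Canyon", "calcitic", True)] * 2   # mostly molds
    spec += [("echinoderm", "Paris Canyon", "calcitic", False)] * 3
    spec += [("brachiopod", "Paris Canyon", "phosphatic", False)] * 5
    spec += [("arthropod", "Paris Canyon", "phosphatic", False)] * 11
    spec += [("arthropod", "LAK", "phosphatic", False)] * 3
    spec += [("coleoid", "LAK", "phosphatic", False)]
    spec += [("actinopterygian", "Stewart Canyon", "carbonaceous", False)]
    spec += [("brachiopod", "Stewart Canyon", "carbonaceous", False)]
    spec += [("arthropod", "Stewart Canyon", "carbonaceous", False)]
    spec += [("sponge", "Immigrant Canyon", "phosphatic", False)]
    spec += [("echinoderm", "Immigrant Canyon", "calcitic", False)]
    spec += [("sarcopterygian", "Georgetown", "phosphatic", False)]
    spec += [("arthropod", "NoName", "carbonaceous", False)]
    spec += [("echinoderm", "Montello Canyon", "calcitic", False)]
    assert len(spec) == 38
    # controls: one echinoderm and one arthropod from the best-sampled site,
    # measured in all three sessions
    controls = {"SPEC08", "SPEC13"}
    out = []
    for i, (clade, site, mineralogy, ppa) in enumerate(spec, start=1):
        sid = f"SPEC{i:02d}"
        out.append(
            SpecimenDesign(
                specimen_id=sid, clade=clade, site=site, mineralogy=mineralogy,
                poorly_preserved=ppa, control=sid in controls,
            )
        )
    return tuple(out)


def default_scenario(seed: int = 0) -> SimulationScenario:
    """The default study-design scenario (38 specimens, 3 sessions, 2 controls)."""
    sessions = (
        SessionEffect(name="DiffAbs-2018", scatter_amp=3.0, offset_amp=0.5,
                      sens_slope=0.00, sens_bump_amp=0.00, jitter_kev=0.025),
        SessionEffect(name="PUMA-2021", scatter_amp=9.0, offset_amp=2.0,
                      sens_slope=0.12, sens_bump_amp=0.08, sens_bump_center=8.0, jitter_kev=0.025),
        SessionEffect(name="PUMA-2024", scatter_amp=6.0, offset_amp=1.2,
                      sens_slope=-0.10, sens_bump_amp=0.06, sens_bump_center=13.0, jitter_kev=0.02),
    )
    profiles = {c: {**p, **CONSTANT_TRACE} for c, p in _CLADE_PROFILES.items()}
    return SimulationScenario(
        clade_profiles=profiles,
        clade_blend=dict(_CLADE_BLEND),
        design=_study_design(),
        sessions=sessions,
        detector=DetectorModel(),
        seed=seed,
    )


def _line_table() -> pd.DataFrame:
    lines = emission_lines()
    return lines[lines["energy_kev"] < EXCITATION_KEV]


def simulate_spectrum(
    concentrations: Mapping[str, float],
    scenario: SimulationScenario,
    zone_type: str,
    session: str,
    rng: np.random.Generator,
    zone_id: str = "synthetic",
    noiseless: bool = False,
    jitter: float | None = None,
    include_background: bool = True,
) -> Spectrum:
    """Simulate one per-zone mean spectrum under the scenario's physics."""
    ses = next((s for s in scenario.sessions if s.name == session), None)
    if ses is None:
        raise ValueError(f"session {session!r} not in scenario")
    det = scenario.detector
    lines = _line_table()
    known = set(lines["element"])
    missing = [e for e in concentrations if e not in known]
    if missing:
        raise ValueError(f"element(s) without line data: {missing}")
    energy = _CHANNELS
    lam = np.zeros_like(energy)
    if include_background:
        lam += (
            scenario.background_amp * np.exp(-energy / scenario.background_tau)
            + scenario.background_const
        )
    for el, conc in concentrations.items():
        if conc <= 0:
            continue
        for _, row in lines[lines["element"] == el].iterrows():
            e_line = row["energy_kev"]
            ratio = det.kbeta_ratio if row["line"] == "Kb1" else 1.0
            sigma = det.sigma(e_line)
            area = conc * ratio
            lam += area * np.exp(-0.5 * ((energy - e_line) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi)) * CHANNEL_STEP
            e_esc = e_line - SI_ESCAPE_KEV
            if e_esc > CHANNEL_LO:
                s_esc = det.sigma(e_esc)
                lam += (
                    area * det.escape_fraction
                    * np.exp(-0.5 * ((energy - e_esc) / s_esc) ** 2) / (s_esc * np.sqrt(2 * np.pi)) * CHANNEL_STEP
                )
    lam *= ses.sensitivity(energy)
    lam += ses.offset(energy)
    lam *= scenario.exposure
    if noiseless:
        counts = lam
    else:
        counts = rng.poisson(lam).astype(float)
    if jitter is None:
        jitter = float(rng.uniform(-ses.jitter_kev, ses.jitter_kev))
    return Spectrum(zone_id=zone_id, energy=energy + jitter, counts=counts)


def _perturb(rng: np.random.Generator, profile: Mapping[str, float], cv: float) -> dict[str, float]:
    if cv <= 0:
        return dict(profile)
    sigma = np.sqrt(np.log1p(cv**2))
    return {el: c * rng.lognormal(-sigma**2 / 2, sigma) for el, c in profile.items()}


def _design_means(scenario: SimulationScenario) -> dict[str, float]:
    """Across-class design mean of each element (clade profiles + mid-gradient sediment)."""
    profiles = list(scenario.clade_profiles.values()) + [sediment_composition(0.5)]
    elements = sorted({e for p in profiles for e in p})
    return {el: float(np.mean([p.get(el, 0.0) for p in profiles])) for el in elements}


def _flatten(comp: Mapping[str, float], scenario: SimulationScenario, means: Mapping[str, float]) -> dict[str, float]:
    if scenario.flatten_except is None:
        return dict(comp)
    keep = set(scenario.flatten_except)
    return {el: (c if el in keep else means.get(el, c)) for el, c in comp.items()}


def _blend(fossil: Mapping[str, float], sediment: Mapping[str, float], b: float) -> dict[str, float]:
    els = sorted(set(fossil) | set(sediment))  # sorted: rng consumption must not depend on hash order
    return {e: (1.0 - b) * fossil.get(e, 0.0) + b * sediment.get(e, 0.0) for e in els}


def simulate_dataset(scenario: SimulationScenario, outdir: str | Path | None = None) -> SyntheticDataset:
    """Simulate the full labelled dataset (spectra + manifest + ground truth).

    Bit-for-bit reproducible from (scenario, scenario.seed).  With ``outdir``,
    spectrum files and ``manifest.csv`` / ``truth.csv`` are also written.
    """
    rng = np.random.default_rng(scenario.seed)
    site_rng = np.random.default_rng(scenario.seed + 1)
    design_means = _design_means(scenario)
    # deterministic per-(site, element) small concentration perturbations
    sites = sorted({d.site for d in scenario.design})
    elements = sorted({e for p in scenario.clade_profiles.values() for e in p})
    sigma_site = np.sqrt(np.log1p(scenario.site_cv**2)) if scenario.site_cv > 0 else 0.0
    site_factor = {
        (site, el): float(site_rng.lognormal(-sigma_site**2 / 2, sigma_site)) if sigma_site else 1.0
        for site in sites
        for el in elements
    }
    session_names = [s.name for s in scenario.sessions]
    spectra: list[Spectrum] = []
    manifest_rows = []
    truth_rows = []
    n_noncontrol = 0
    for d in scenario.design:
        g = float(rng.uniform(0.0, 1.0))
        clade_mean = {el: c * site_factor[(d.site, el)] for el, c in scenario.clade_profiles[d.clade].items()}
        specimen_conc = _perturb(rng, clade_mean, scenario.between_specimen_cv)
        blend = scenario.poorly_preserved_blend if d.poorly_preserved else scenario.clade_blend[d.clade]
        if d.control:
            zone_sessions = list(session_names)
        else:
            zone_sessions = [session_names[n_noncontrol % len(session_names)]]
            n_noncontrol += 1
        for zone_type, zone_no in [("fossil", 1), ("fossil", 2), ("fossil", 3),
                                   ("sediment", 1), ("sediment", 2), ("sediment", 3)]:
            zone_id = f"{d.specimen_id}-{zone_type[:3]}{zone_no}"
            g_zone = float(np.clip(g + rng.normal(0.0, 0.03), 0.0, 1.0))
            sed = _flatten(sediment_composition(g_zone), scenario, design_means)
            if zone_type == "sediment":
                base = sed
                true_blend = 1.0
            else:
                base = _blend(_flatten(specimen_conc, scenario, design_means), sed, blend)
                true_blend = blend
            zone_conc = _perturb(rng, base, scenario.within_specimen_cv)
            for session in zone_sessions:
                spec = simulate_spectrum(
                    zone_conc, scenario, zone_type, session, rng,
                    zone_id=f"{zone_id}@{session}",
                )
                spec = Spectrum(zone_id, spec.energy, spec.counts)
                spectra.append(spec)
                manifest_rows.append(
                    {
                        "zone_id": zone_id,
                        "file": f"{zone_id}_{session}.csv",
                        "specimen_id": d.specimen_id,
                        "site": d.site,
                        "clade": d.clade,
                        "zone_type": zone_type,
                        "session": session,
                        "mineralogy": "matrix" if zone_type == "sediment" else d.mineralogy,
                    }
                )
                truth_rows.append(
                    {
                        "zone_id": zone_id,
                        "session": session,
                        "specimen_id": d.specimen_id,
                        "clade": d.clade,
                        "zone_type": zone_type,
                        "poorly_preserved": d.poorly_preserved,
                        "control": d.control,
                        "g": g_zone,
                        "blend": true_blend,
                        **{f"conc_{el}": zone_conc.get(el, 0.0) for el in elements},
                    }
                )
    manifest = validate_manifest(pd.DataFrame(manifest_rows), name="synthetic manifest")
    truth = pd.DataFrame(truth_rows)
    dataset = SyntheticDataset(spectra=spectra, manifest=manifest, truth=truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for spec, row in zip(dataset.spectra, manifest_rows):
            write_spectrum(spec, outdir / row["file"])
        manifest.to_csv(outdir / "manifest.csv", index=False)
        truth.to_csv(outdir / "truth.csv", index=False)
    return dataset


def differing_elements(scenario: SimulationScenario, rel_spread: float = 0.25) -> tuple[set[str], set[str]]:
    """Split the scenario's elements into (differing, constant) across classes.

    Classes are the clade profiles plus the two sediment gradient poles
    (g = 0 calcitic, g = 1 ferruginous).  An element *differs* when the
    relative spread of its design concentrations, (max - min) / mean, exceeds
    ``rel_spread``.  Read from the generating design, not from noisy draws,
    so the answer is deterministic.  Under ``flatten_except`` only the listed
    elements can differ.
    """
    sed_poles = [sediment_composition(0.0), sediment_composition(1.0)]
    elements = sorted({e for p in scenario.clade_profiles.values() for e in p})
    keep = None if scenario.flatten_except is None else set(scenario.flatten_except)
    differing: set[str] = set()
    constant: set[str] = set()
    for el in elements:
        vals = np.array(
            [p.get(el, 0.0) for p in scenario.clade_profiles.values()]
            + [p.get(el, 0.0) for p in sed_poles]
        )
        mean = vals.mean()
        spread = (vals.max() - vals.min()) / mean if mean > 0 else 0.0
        is_diff = spread > rel_spread and (keep is None or el in keep)
        (differing if is_diff else constant).add(el)
    return differing, constant
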