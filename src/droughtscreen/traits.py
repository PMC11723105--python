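"""Derived physiological, gas-exchange, fluorescence and stomatal traits.

Every trait used by the screening pipeline that is not read directly off an
instrument is computed here from its raw measurements: gravimetric leaf-water
indices (LRWC, ELWR, RWL), electrolyte-leakage membrane stability (CMS),
canopy temperature depression (CTD), apparent mesophyll conductance and leaf
water-use efficiency from IRGA readings, PAM chlorophyll-fluorescence
parameters, and anatomical stomatal indices including the theoretical maximum
stomatal diffusive conductance g_s.max of Franks & Beerling.

Scalar formulas accept floats or numpy arrays and broadcast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TRAIT_NAMES",
    "LOWER_BETTER_DEFAULT",
    "StomatalGeometry",
    "lrwc",
    "elwr",
    "rwl",
    "cms",
    "ctd",
    "mesophyll_conductance",
    "wue_leaf",
    "chlf_parameters",
    "stomatal_indices",
    "gs_max",
    "relative_values",
    "percent_change",
    "derive_observation_table",
]

#: Canonical names of the 37 analysed traits, grouped by assay family:
#: 6 physiological, 7 gas exchange, 6 PSII fluorescence, 6 stomatal,
#: 3 reactive-oxygen markers, 7 osmolytes, 2 yield.
TRAIT_NAMES: tuple[str, ...] = (
    "LRWC", "ELWR", "RWL", "SPAD", "CTD", "CMS",
    "Pn", "gs", "gm", "Tr", "Ci", "VPD_LA", "WUE_L",
    "Fv_Fm", "Fv_Fo", "Phi_PSII", "qP", "NPQ", "ETR",
    "SD", "SS", "AS", "SAI", "Sgs", "gs_max",
    "MDA", "H2O2", "MG",
    "Pro", "Orn", "GB", "TFAA", "Tre", "Suc", "TSS",
    "BY", "GY",
)

#: Traits for which a *decrease* is the breeding target (all others are
#: higher-better).  User-overridable wherever a direction vector is accepted.
LOWER_BETTER_DEFAULT: frozenset[str] = frozenset(
    {"ELWR", "Ci", "VPD_LA", "WUE_L", "NPQ", "MDA", "H2O2", "MG"}
)

# physical constants for g_s.max (Franks & Beerling convention)
WATER_VAPOUR_DIFFUSIVITY_25C = 2.82e-5  # m^2 s^-1
AIR_MOLAR_VOLUME_25C = 0.0245  # m^3 mol^-1 (24.5 L mol^-1)


class TraitDomainError(ValueError):
    """Raised when raw measurements violate a formula's domain."""


def _check(cond, msg: str) -> None:
    if not np.all(cond):
        raise TraitDomainError(msg)


def lrwc(fw, tw, dw):
    """Leaf relative water content, % = (FW−DW)/(TW−DW)×100.

    FW fresh, TW turgid (rehydrated) and DW oven-dry leaf mass in grams.
    """
    fw, tw, dw = map(np.asarray, (fw, tw, dw))
    _check(tw > dw, "LRWC undefined: turgid weight must exceed dry weight")
    _check((fw >= dw) & (fw <= tw), "LRWC requires DW <= FW <= TW")
    return (fw - dw) / (tw - dw) * 100.0


def elwr(fw, ww):
    """Excised-leaf water retention, % = [1 − (FW−WW)/FW]×100 = WW/FW×100."""
    fw, ww = map(np.asarray, (fw, ww))
    _check(fw > 0, "ELWR undefined for zero fresh weight")
    _check((ww > 0) & (ww <= fw), "ELWR requires 0 < WW <= FW")
    return (1.0 - (fw - ww) / fw) * 100.0


def rwl(fw, ww, dw, *, per_dry_mass: bool = True):
    """Relative water loss of an excised leaf after wilting.

    Default convention normalises the lost water by dry mass,
    RWL% = (FW−WW)/DW×100; ``per_dry_mass=False`` selects the
    fresh-mass-normalised variant (FW−WW)/FW×100.
    """
    fw, ww, dw = map(np.asarray, (fw, ww, dw))
    _check(dw > 0, "RWL undefined for zero dry weight")
    _check((ww > dw) & (ww <= fw), "RWL requires DW < WW <= FW")
    if per_dry_mass:
        return (fw - ww) / dw * 100.0
    return (fw - ww) / fw * 100.0


def cms(c1, c2):
    """Cell membrane stability, % = [1 − C1/C2]×100.

    C1 is the electrolyte conductivity after the mild (40 °C) incubation and
    C2 after complete disruption (100 °C); 100 % means no leakage.
    """
    c1, c2 = map(np.asarray, (c1, c2))
    _check(c2 > 0, "CMS undefined for zero reference conductivity")
    _check((c1 >= 0) & (c1 <= c2), "CMS requires 0 <= C1 <= C2")
    return (1.0 - c1 / c2) * 100.0


def ctd(at, ct):
    """Canopy temperature depression, °C = air − canopy (positive = cooler canopy)."""
    at, ct = map(np.asarray, (at, ct))
    _check(np.isfinite(at) & np.isfinite(ct), "CTD requires finite temperatures")
    return at - ct


def mesophyll_conductance(pn, ci):
    """Apparent mesophyll conductance g_m = P_n/C_i (mol m⁻² s⁻¹)."""
    pn, ci = map(np.asarray, (pn, ci))
    _check(ci > 0, "g_m undefined for non-positive intercellular CO2")
    return pn / ci


def wue_leaf(pn, tr):
    """Instantaneous leaf water-use efficiency WUE_L = P_n/T_r."""
    pn, tr = map(np.asarray, (pn, tr))
    _check(tr > 0, "WUE_L undefined for non-positive transpiration")
    return pn / tr


def chlf_parameters(
    f_o, f_m, f_o_prime, f_m_prime, f_s, ppfd,
    *, leaf_absorptance: float = 0.84, psii_fraction: float = 0.5,
) -> dict[str, np.ndarray]:
    """PAM chlorophyll-fluorescence parameters.

    Dark-adapted F_o/F_m and light-adapted F'_o/F'_m/F_s give:

    * ``Fv_Fm``  = (F_m − F_o)/F_m, maximal PSII quantum efficiency;
    * ``Fv_Fo``  = (F_m − F_o)/F_o, maximum energy-conversion potential;
    * ``Phi_PSII`` = (F'_m − F_s)/F'_m, operating quantum yield;
    * ``qP``   = (F'_m − F_s)/(F'_m − F'_o), photochemical quenching;
    * ``NPQ``  = (F_m − F'_m)/F'_m, non-photochemical quenching;
    * ``ETR``  = Phi_PSII × PPFD × absorptance × PSII fraction.

    The absorptance (0.84) and the fraction of quanta reaching PSII (0.5)
    are the conventional leaf constants and are exposed as keywords.
    """
    f_o, f_m, f_o_prime, f_m_prime, f_s, ppfd = map(
        np.asarray, (f_o, f_m, f_o_prime, f_m_prime, f_s, ppfd)
    )
    _check((f_o > 0) & (f_m > f_o), "fluorescence requires 0 < F_o < F_m")
    _check((f_o_prime > 0) & (f_m_prime > f_o_prime),
           "fluorescence requires 0 < F'_o < F'_m")
    _check(f_s < f_m_prime, "steady-state F_s must stay below F'_m")
    phi_psii = (f_m_prime - f_s) / f_m_prime
    return {
        "Fv_Fm": (f_m - f_o) / f_m,
        "Fv_Fo": (f_m - f_o) / f_o,
        "Phi_PSII": phi_psii,
        "qP": (f_m_prime - f_s) / (f_m_prime - f_o_prime),
        "NPQ": (f_m - f_m_prime) / f_m_prime,
        "ETR": phi_psii * ppfd * leaf_absorptance * psii_fraction,
    }


@dataclass(frozen=True)
class StomatalGeometry:
    """Stomatal anatomy averaged over the adaxial and abaxial surfaces.

    Attributes
    ----------
    sd : stomatal density, stomata mm⁻².
    ss : stomatal size = guard-cell length × width, µm².
    as_ : aperture space = pore length × width, µm².
    pore_length : µm (the *p* of the g_s.max formula).
    guard_width : µm (pore depth l = guard_width/2).
    """

    sd: float
    ss: float
    as_: float
    pore_length: float
    guard_width: float

    def __post_init__(self):
        for name in ("sd", "ss", "as_", "pore_length", "guard_width"):
            if not np.all(np.asarray(getattr(self, name)) > 0):
                raise TraitDomainError(f"stomatal geometry field {name!r} must be > 0")

    @property
    def a_max(self):
        """Maximum open-pore area π(p/2)², m²."""
        p_m = np.asarray(self.pore_length) * 1e-6
        return math.pi * (p_m / 2.0) ** 2

    @property
    def pore_depth(self):
        """Pore depth of the fully open stoma, W/2, m."""
        return np.asarray(self.guard_width) * 1e-6 / 2.0


def stomatal_indices(geometry: StomatalGeometry, g_s) -> dict[str, np.ndarray]:
    """Integrative stomatal metrics.

    ``SAI`` (stomatal area index) = SD × SS, expressed in mm² stomata per mm²
    leaf (SS is converted from µm²); ``Sgs`` (specific stomatal conductance)
    = g_s / SD.
    """
    sd = np.asarray(geometry.sd)
    _check(sd > 0, "stomatal indices undefined at zero stomatal density")
    return {
        "SAI": sd * np.asarray(geometry.ss) * 1e-6,
        "Sgs": np.asarray(g_s) / sd,
    }


def gs_max(
    sd, pore_length, guard_width,
    *, d: float = WATER_VAPOUR_DIFFUSIVITY_25C,
    v: float = AIR_MOLAR_VOLUME_25C,
    boundary_factor: float = 1.6,
):
    """Theoretical maximum stomatal diffusive conductance, mol m⁻² s⁻¹.

    Anatomical (Franks & Beerling) conductance::

        g_s.max = d · SD · a_max / ( 1.6 · v · ( l + (π/2)·sqrt(a_max/π) ) )

    with ``a_max = π(p/2)²`` the fully open pore area and ``l = W/2`` the
    pore depth.  Inputs use field units — SD in stomata mm⁻², pore length
    *p* and guard-cell width *W* in µm — and are converted to SI here.

    Parameters
    ----------
    d : water-vapour diffusivity in air at 25 °C, m² s⁻¹.
    v : molar volume of air at 25 °C, m³ mol⁻¹ (0.0245 by default; pass 24.5
        to reproduce a literal "m³ mol⁻¹" reading, which shrinks the result
        by 10³).
    boundary_factor : the 1.6 diffusivity ratio in the denominator; set to
        1.0 to drop it.
    """
    sd, p, w = map(np.asarray, (sd, pore_length, guard_width))
    _check((sd > 0) & (p > 0) & (w > 0), "g_s.max requires positive geometry")
    sd_m2 = sd * 1e6
    a_max = math.pi * (p * 1e-6 / 2.0) ** 2
    depth = w * 1e-6 / 2.0
    denom = boundary_factor * v * (depth + (math.pi / 2.0) * np.sqrt(a_max / math.pi))
    return d * sd_m2 * a_max / denom


# ---------------------------------------------------------------------------
# relative values and percent changes (genotype-mean level)
# ---------------------------------------------------------------------------

def relative_values(control_means: pd.DataFrame, drought_means: pd.DataFrame) -> pd.DataFrame:
    """Ratio of drought to control genotype means, trait by trait.

    Both inputs are genotype × trait matrices with matching labels.  Traits
    whose control mean is zero for any genotype are excluded with a warning
    (the ratio is undefined there).
    """
    control_means, drought_means = control_means.align(drought_means, join="inner")
    if control_means.empty:
        raise ValueError("no common genotypes/traits between the two matrices")
    bad = (control_means == 0).any(axis=0)
    if bad.any():
        import warnings

        warnings.warn(
            "dropping traits with zero control mean: "
            + ", ".join(map(str, control_means.columns[bad])),
            stacklevel=2,
        )
        control_means = control_means.loc[:, ~bad]
        drought_means = drought_means.loc[:, ~bad]
    return drought_means / control_means


def percent_change(control, drought):
    """Signed percent change (drought − control)/control × 100."""
    control, drought = np.asarray(control, float), np.asarray(drought, float)
    _check(control != 0, "percent change undefined for zero control value")
    return (drought - control) / control * 100.0


# ---------------------------------------------------------------------------
# bundle -> long observation table
# ---------------------------------------------------------------------------

_KEY = ["genotype", "condition", "block"]

#: unit attached to each derived trait in the long output
TRAIT_UNITS: dict[str, str] = {
    "LRWC": "%", "ELWR": "%", "RWL": "%", "SPAD": "index", "CTD": "degC",
    "CMS": "%",
    "Pn": "umol m-2 s-1", "gs": "mol m-2 s-1", "gm": "mol m-2 s-1",
    "Tr": "mmol m-2 s-1", "Ci": "umol mol-1", "VPD_LA": "kPa",
    "WUE_L": "umol mmol-1",
    "Fv_Fm": "ratio", "Fv_Fo": "ratio", "Phi_PSII": "ratio", "qP": "ratio",
    "NPQ": "ratio", "ETR": "umol m-2 s-1",
    "SD": "stomata mm-2", "SS": "um2", "AS": "um2",
    "SAI": "mm2 mm-2", "Sgs": "mol m-2 s-1 mm2", "gs_max": "mol m-2 s-1",
    "MDA": "nmol g-1 FW", "H2O2": "umol g-1 FW", "MG": "umol g-1 FW",
    "Pro": "umol g-1 FW", "Orn": "umol g-1 FW", "GB": "umol g-1 FW",
    "TFAA": "mg g-1 FW", "Tre": "umol g-1 FW", "Suc": "mg g-1 FW",
    "TSS": "mg g-1 FW", "BY": "t ha-1", "GY": "t ha-1",
}


def derive_observation_table(bundle, *, rwl_per_dry_mass: bool = True,
                             gs_max_kwargs: dict | None = None) -> pd.DataFrame:
    """Compute every derivable trait from a raw-measurement bundle.

    ``bundle`` is a :class:`droughtscreen.synthetic.RawMeasurementBundle` (or
    any object with the same per-assay DataFrames).  Returns a long table
    with columns genotype, condition, block, trait, value, unit; direct
    assay readings carried in ``bundle.direct`` (SPAD, biochemistry, yield)
    pass through unchanged.
    """
    gs_max_kwargs = gs_max_kwargs or {}
    frames: list[pd.DataFrame] = []

    def emit(keys: pd.DataFrame, trait: str, values) -> None:
        out = keys[_KEY].copy()
        out["trait"] = trait
        out["value"] = np.asarray(values, float)
        out["unit"] = TRAIT_UNITS.get(trait, "")
        frames.append(out)

    lw = bundle.leaf_water
    emit(lw, "LRWC", lrwc(lw["FW"], lw["TW"], lw["DW"]))
    wl = bundle.wilting
    emit(wl, "ELWR", elwr(wl["FW"], wl["WW"]))
    emit(wl, "RWL", rwl(wl["FW"], wl["WW"], wl["DW"], per_dry_mass=rwl_per_dry_mass))
    cond = bundle.conductivity
    emit(cond, "CMS", cms(cond["C1"], cond["C2"]))
    temp = bundle.canopy_temperature
    emit(temp, "CTD", ctd(temp["AT"], temp["CT"]))

    ge = bundle.gas_exchange
    for raw in ("Pn", "gs", "Tr", "Ci", "VPD_LA"):
        emit(ge, raw, ge[raw])
    emit(ge, "gm", mesophyll_conductance(ge["Pn"], ge["Ci"]))
    emit(ge, "WUE_L", wue_leaf(ge["Pn"], ge["Tr"]))

    fl = bundle.fluorescence
    for trait, values in chlf_parameters(
        fl["Fo"], fl["Fm"], fl["Fo_prime"], fl["Fm_prime"], fl["Fs"], fl["PPFD"]
    ).items():
        emit(fl, trait, values)

    st = bundle.stomata
    geom = StomatalGeometry(
        sd=st["SD"].to_numpy(),
        ss=(st["guard_length"] * st["guard_width"]).to_numpy(),
        as_=(st["pore_length"] * st["pore_width"]).to_numpy(),
        pore_length=st["pore_length"].to_numpy(),
        guard_width=st["guard_width"].to_numpy(),
    )
    emit(st, "SD", geom.sd)
    emit(st, "SS", geom.ss)
    emit(st, "AS", geom.as_)
    gs_per_plot = (
        ge.set_index(_KEY).loc[st.set_index(_KEY).index, "gs"].to_numpy()
    )
    idx = stomatal_indices(geom, gs_per_plot)
    emit(st, "SAI", idx["SAI"])
    emit(st, "Sgs", idx["Sgs"])
    emit(st, "gs_max",
         gs_max(geom.sd, geom.pore_length, geom.guard_width, **gs_max_kwargs))

    direct = bundle.direct.copy()
    if "unit" not in direct.columns:
        direct["unit"] = direct["trait"].map(TRAIT_UNITS).fillna("")
    frames.append(direct[_KEY + ["trait", "value", "unit"]])

    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(_KEY[:1] + ["trait"] + _KEY[1:], kind="stable",
                           ignore_index=True)
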