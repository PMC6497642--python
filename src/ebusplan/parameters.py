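"""Model constants for intratumoral cisplatin transport.

The tumor is modelled as coincident extracellular and intracellular
compartments (volume fractions ``alpha_e + alpha_i = 1``) coupled to a single
well-mixed systemic fluid compartment of volume ``V_f``.  Drug diffuses
through the extracellular space with coefficient ``D`` and is lost to the
intracellular space (rate ``k_i``, an irreversible sink via DNA binding) and
to the fluid space (rate ``k_f``), from which it is cleared renally at rate
``k_r``.

Canonical internal units are mg, cm and s; concentrations are mg/cm^3
(identical to mg/mL).  Config files may give ``V_f`` in litres via the
``V_f_L`` key.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

#: Prefactor of the empirical molecular-weight law for drug diffusion in
#: soft tissue at 37 C, cm^2/s at MW = 1 Da.
DIFFUSION_LAW_PREFACTOR = 1.778e-4
DIFFUSION_LAW_EXPONENT = -0.75

#: Molecular weight of cisplatin, Da.
CISPLATIN_MW = 300.0

#: Cisplatin uptake rate into tumor cells reported for head/neck and gastric
#: carcinoma lines, 1/s.  Used to split a fitted k_i + k_f into components.
LITERATURE_K_I = 1.05e-4

#: Renal clearance rate from the ~30 min biological half-life of cisplatin.
DEFAULT_RENAL_HALF_LIFE_S = 1800.0

_FOUR_PI = 4.0 * math.pi


def diffusion_coefficient(mw: float) -> float:
    """Diffusion coefficient (cm^2/s) from molecular weight (Da).

    Empirical power law ``D = 1.778e-4 * MW**-0.75`` for small molecules in
    normal tissue at body temperature.  For cisplatin (300 Da) this gives
    2.47e-6 cm^2/s.
    """
    if mw <= 0:
        raise ValueError(f"molecular weight must be positive, got {mw}")
    return DIFFUSION_LAW_PREFACTOR * mw**DIFFUSION_LAW_EXPONENT


def renal_rate_from_half_life(half_life_s: float) -> float:
    """First-order renal clearance constant (1/s) from a half-life (s)."""
    if half_life_s <= 0:
        raise ValueError(f"half-life must be positive, got {half_life_s}")
    return math.log(2.0) / half_life_s


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants, volumes and fractions governing the model.

    Parameters
    ----------
    D : float
        Extracellular diffusion coefficient, cm^2/s.
    k_i : float
        Extracellular -> intracellular uptake rate constant, 1/s.
    k_f : float
        Extracellular -> fluid (vascular) clearance rate constant, 1/s.
    k_r : float
        Renal clearance rate constant of the fluid compartment, 1/s.
    V_f : float
        Fluid-space (systemic distribution) volume, cm^3.
    alpha_e, alpha_i : float
        Extracellular / intracellular volume fractions; must sum to 1.
    phi_t : float
        Lethal threshold intracellular concentration, mg/cm^3.  A free
        parameter of the planning problem, never hard-coded elsewhere.
    MW : float
        Molecular weight of the injected drug, Da.
    k_f_return : float
        Fluid -> extracellular return rate constant, 1/s.  The analytic
        solution treats the fluid space as a pure sink (return = 0); only the
        finite-difference oracle exercises a nonzero value.
    normalization : str
        ``"mass-conserving"`` (default) uses the 3D heat kernel
        ``(4 pi D t)^{-3/2}``, which makes the spatially integrated
        extracellular mass exactly ``M e^{-(k_i+k_f) t}``.
        ``"literature"`` multiplies every spatial field by ``4 pi``,
        reproducing the ``sqrt(4 pi (D t)^3)`` prefactor convention; placement
        optima and minimal-dose *ratios* are invariant to this global factor.
    """

    D: float
    k_i: float
    k_f: float
    k_r: float
    V_f: float
    alpha_e: float = 0.9
    alpha_i: float = 0.1
    phi_t: float = 5.0e-8
    MW: float = CISPLATIN_MW
    k_f_return: float = 0.0
    normalization: str = "mass-conserving"

    def __post_init__(self) -> None:
        for name in ("k_i", "k_f", "k_r", "k_f_return"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.D <= 0:
            raise ValueError(f"D must be > 0, got {self.D}")
        if self.V_f <= 0:
            raise ValueError(f"V_f must be > 0, got {self.V_f}")
        if not (0.0 < self.alpha_e < 1.0 and 0.0 < self.alpha_i < 1.0):
            raise ValueError("alpha_e and alpha_i must lie in (0, 1)")
        if abs(self.alpha_e + self.alpha_i - 1.0) > 1e-9:
            raise ValueError(
                f"alpha_e + alpha_i must equal 1, got {self.alpha_e + self.alpha_i}"
            )
        if self.phi_t <= 0:
            raise ValueError(f"phi_t must be > 0, got {self.phi_t}")
        if self.normalization not in ("mass-conserving", "literature"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    # -- derived quantities -------------------------------------------------

    @property
    def k_sum(self) -> float:
        """Total extracellular loss rate ``k_i + k_f`` (1/s)."""
        return self.k_i + self.k_f

    @property
    def screening_length(self) -> float:
        """``sqrt(D / (k_i + k_f))`` (cm): decay length of the asymptotic
        intracellular field around an injection site."""
        if self.k_sum == 0:
            return math.inf
        return math.sqrt(self.D / self.k_sum)

    @property
    def field_scale(self) -> float:
        """Global prefactor applied to spatial fields (1 or 4*pi)."""
        return _FOUR_PI if self.normalization == "literature" else 1.0

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    # -- constructors -------------------------------------------------------

    @classmethod
    def patient_fitted(cls, **overrides) -> "ModelParameters":
        """Parameters calibrated against the patient blood series: fitted
        ``k_i + k_f = 2.51e-4`` 1/s and ``V_f = 12.2`` L, literature
        ``k_i = 1.05e-4`` 1/s, ``k_r`` from a 30 min half-life and ``D``
        from the molecular-weight law."""
        k_sum = 2.51e-4
        base = dict(
            D=diffusion_coefficient(CISPLATIN_MW),
            k_i=LITERATURE_K_I,
            k_f=k_sum - LITERATURE_K_I,
            k_r=renal_rate_from_half_life(DEFAULT_RENAL_HALF_LIFE_S),
            V_f=12.2e3,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_config(cls, source) -> "ModelParameters":
        """Build parameters from a YAML/JSON file path or a mapping.

        Recognised keys: ``D`` or ``MW`` (D derived from the power law when
        absent), ``k_i``, ``k_f`` or ``k_sum``, ``k_r`` or
        ``renal_half_life_s``/``renal_half_life_min``, ``V_f`` (cm^3) or
        ``V_f_L`` (litres), ``alpha_i`` (alpha_e = 1 - alpha_i), ``phi_t``,
        ``k_f_return``, ``normalization``.
        """
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
            cfg = (
                json.loads(text)
                if str(source).endswith(".json")
                else yaml.safe_load(text)
            )
        else:
            cfg = dict(source)

        mw = float(cfg.get("MW", CISPLATIN_MW))
        d = float(cfg["D"]) if "D" in cfg else diffusion_coefficient(mw)
        k_i = float(cfg.get("k_i", LITERATURE_K_I))
        if "k_f" in cfg:
            k_f = float(cfg["k_f"])
        elif "k_sum" in cfg:
            k_f = float(cfg["k_sum"]) - k_i
        else:
            k_f = 2.51e-4 - LITERATURE_K_I
        if "k_r" in cfg:
            k_r = float(cfg["k_r"])
        elif "renal_half_life_s" in cfg:
            k_r = renal_rate_from_half_life(float(cfg["renal_half_life_s"]))
        elif "renal_half_life_min" in cfg:
            k_r = renal_rate_from_half_life(60.0 * float(cfg["renal_half_life_min"]))
        else:
            k_r = renal_rate_from_half_life(DEFAULT_RENAL_HALF_LIFE_S)
        if "V_f" in cfg:
            v_f = float(cfg["V_f"])
        elif "V_f_L" in cfg:
            v_f = 1000.0 * float(cfg["V_f_L"])
        else:
            v_f = 12.2e3
        alpha_i = float(cfg.get("alpha_i", 0.1))
        return cls(
            D=d,
            k_i=k_i,
            k_f=k_f,
            k_r=k_r,
            V_f=v_f,
            alpha_e=1.0 - alpha_i,
            alpha_i=alpha_i,
            phi_t=float(cfg.get("phi_t", 5.0e-8)),
            MW=mw,
            k_f_return=float(cfg.get("k_f_return", 0.0)),
            normalization=str(cfg.get("normalization", "mass-conserving")),
        )
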