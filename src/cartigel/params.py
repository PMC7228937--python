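"""Parameter containers for gel phases, bath conditions and experiments.

These are pydantic models so that configuration files map onto them
verbatim (key names are field names) and invalid inputs fail loudly at
construction time rather than deep inside a root finder.
"""

from __future__ import annotations

from pydantic import BaseModel, Field, model_validator

from .constants import T_DEFAULT_K, WATER_MOLAR_VOLUME_CM3


class BathConditions(BaseModel):
    """External solution the gel is equilibrated against.

    salt_concentration is the molar concentration of a fully dissociated
    1:1 salt (mol/L); pH sets the ionization state of weak-acid groups.
    """

    salt_concentration: float = Field(ge=0.0, default=0.1)
    pH: float = Field(ge=0.0, le=14.0, default=7.0)
    temperature: float = Field(gt=0.0, default=T_DEFAULT_K)

    model_config = {"frozen": True}


class NeutralGelParams(BaseModel):
    """Thermodynamic description of a neutral polymer network.

    chi                 Flory-Huggins polymer/solvent interaction parameter.
    crosslink_density   elastic strand concentration in the reference
                        (formation) state, mol/cm^3.
    phi_ref             polymer volume fraction at network formation.
    solvent_molar_volume  cm^3/mol (water: 18).
    """

    chi: float
    crosslink_density: float = Field(ge=0.0)
    phi_ref: float = Field(gt=0.0, lt=1.0)
    solvent_molar_volume: float = Field(gt=0.0, default=WATER_MOLAR_VOLUME_CM3)
    label: str = ""

    model_config = {"frozen": True}

    @property
    def is_charged(self) -> bool:
        return False


class PolyelectrolyteGelParams(NeutralGelParams):
    """Weak polyacid network: neutral-gel fields plus ionization.

    The fixed-charge density at volume fraction phi is
    ``alpha * ionizable_fraction * effective_charge_fraction * phi / monomer_molar_volume``
    with alpha the Henderson-Hasselbalch degree of dissociation.
    effective_charge_fraction lumps counterion condensation and other
    non-idealities into a single attenuation factor; it is a calibration
    knob, not a measured quantity.
    """

    pKa: float = 4.5
    monomer_molar_volume: float = Field(gt=0.0, default=48.0)
    ionizable_fraction: float = Field(ge=0.0, le=1.0, default=1.0)
    effective_charge_fraction: float = Field(ge=0.0, le=1.0, default=0.3)

    @property
    def is_charged(self) -> bool:
        return True


GelParams = NeutralGelParams  # common base for annotations


class CompositeParams(BaseModel):
    """Two-phase composite: neutral matrix encapsulating charged filler.

    filler_polymer_fraction is the fraction of the total polymer that is
    filler (volume basis); 0.5 corresponds to a 1:1 mixture.
    """

    matrix: NeutralGelParams
    filler: PolyelectrolyteGelParams
    filler_polymer_fraction: float = Field(gt=0.0, lt=1.0, default=0.5)
    label: str = ""

    model_config = {"frozen": True}


class ExperimentDesign(BaseModel):
    """Design of a simulated osmotic-stress (dialysis) experiment.

    stress_ladder    external osmotic pressures in kPa, strictly increasing.
    noise_cv         coefficient of variation of the multiplicative
                     (lognormal) measurement noise applied to hydration.
    replicates       independent gels per stress level.
    seed             integer seed; all randomness derives from it.
    """

    stress_ladder: list[float]
    noise_cv: float = Field(ge=0.0, default=0.02)
    replicates: int = Field(ge=1, default=1)
    seed: int = 0

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check_ladder(self) -> "ExperimentDesign":
        lad = self.stress_ladder
        if len(lad) == 0:
            raise ValueError("stress_ladder must not be empty")
        if any(p < 0 for p in lad):
            raise ValueError("stress_ladder pressures must be non-negative")
        if any(b <= a for a, b in zip(lad, lad[1:])):
            raise ValueError("stress_ladder must be strictly increasing")
        return self


def gel_params_from_dict(d: dict) -> NeutralGelParams:
    """Build the right gel-parameter type from a plain mapping.

    A mapping containing any polyelectrolyte-only key (pKa,
    monomer_molar_volume, ionizable_fraction, effective_charge_fraction)
    is read as a charged gel, otherwise as a neutral one.
    """
    charged_keys = {
        "pKa",
        "monomer_molar_volume",
        "ionizable_fraction",
        "effective_charge_fraction",
    }
    if charged_keys & set(d):
        return PolyelectrolyteGelParams(**d)
    return NeutralGelParams(**d)
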