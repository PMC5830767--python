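"""Physical constants and unit conventions.

Package-wide units: length in Å, momentum transfer in Å⁻¹, energy in meV,
temperature in K, intensities in detector counts.
"""

from __future__ import annotations

#: Boltzmann constant in meV per kelvin.
K_B_MEV_PER_K: float = 0.0861733

#: Default sample temperature (30 °C, fluid phase of DMPC/cholesterol stacks).
DEFAULT_TEMPERATURE_K: float = 303.15

#: Electrons per neutral atom, for electron-density weighting.
ELECTRONS: dict[str, int] = {
    "H": 1, "D": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16, "SI": 14,
}

#: Coherent neutron scattering lengths, fm. Note the sign flip H -> D that
#: makes deuteration a contrast knob.
COHERENT_SCATTERING_LENGTH_FM: dict[str, float] = {
    "H": -3.7390, "D": 6.671, "C": 6.6460, "N": 9.36, "O": 5.803,
    "P": 5.13, "S": 2.847, "SI": 4.1491,
}


def thermal_energy(temperature: float) -> float:
    """k_B·T in meV.

    Parameters
    ----------
    temperature : float
        Absolute temperature in K; must be positive.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return K_B_MEV_PER_K * temperature
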