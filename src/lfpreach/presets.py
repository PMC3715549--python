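"""Stylized cell presets standing in for reconstructed cortical neurons.

Dimensions are plausible for the respective cell classes but are design
choices of this package, not measurements: the templates exist to provide the
qualitative geometry (deep pyramidal cells with long apical trunks, superficial
pyramidal cells with shorter ones, stellate cells with no polarity) that
controls extracellular-potential generation.
"""

from __future__ import annotations

from .morphology import Morphology, make_stylized_pyramidal, make_stylized_stellate


def l5_like(soma_depth: float = 0.0) -> Morphology:
    """Deep (layer-5-like) pyramidal template: long apical trunk."""
    return make_stylized_pyramidal(
        soma_diam=20.0, trunk_length=800.0, trunk_diam=4.0,
        n_basal=6, basal_length=250.0, basal_diam=2.0,
        n_tuft=6, tuft_length=200.0, tuft_diam=1.5,
        soma_depth=soma_depth,
    )


def l3_like(soma_depth: float = 0.0) -> Morphology:
    """Superficial (layer-3-like) pyramidal template: shorter trunk."""
    return make_stylized_pyramidal(
        soma_diam=15.0, trunk_length=400.0, trunk_diam=3.0,
        n_basal=5, basal_length=180.0, basal_diam=1.5,
        n_tuft=5, tuft_length=120.0, tuft_diam=1.0,
        soma_depth=soma_depth,
    )


def l4_like(soma_depth: float = 0.0) -> Morphology:
    """Layer-4-like spiny-stellate template: isotropic dendrites."""
    return make_stylized_stellate(
        n_dendrites=10, dendrite_length=200.0, dendrite_diam=1.5,
        soma_diam=15.0, soma_depth=soma_depth,
    )


PRESETS = {"L5-like": l5_like, "L3-like": l3_like, "L4-like": l4_like}


def get_preset(name: str, soma_depth: float = 0.0) -> Morphology:
    try:
        return PRESETS[name](soma_depth=soma_depth)
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
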