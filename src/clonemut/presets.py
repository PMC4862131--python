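"""Treatment-like preset spectra and indel context models for the simulator.

The presets are readable approximations of the published figure-level
proportions for the three mutagenic conditions studied in the clone
cohorts, expressed as a 96-channel probability vector (class weight x
independent 5'/3' flank weights) plus weighted indel context patterns:

* ``mock`` -- spontaneous mutagenesis: C>T and C>A dominated, with a strong
  excess of C>T at CpG (NCG>NTG) from 5-methylcytosine deamination.
* ``cisplatin`` -- 57 % C>A with the NCC>NAC (3' C), NCT>NAT and NTC>NAC
  context enrichments expected from adenine mis-incorporation opposite the
  3' guanine of GG/AG/GA intrastrand crosslinks; a sizeable fraction of
  events emitted as adjacent dinucleotide pairs; T insertions preceded by
  GG and followed by T; deletions removing bases of AG/GG motifs.
* ``cyclophosphamide`` -- T>A and C>T dominated with an NTT context
  preference (CTT/TTT) and few indels.

These encode the study conditions qualitatively; they are approximations of
the published proportions, not ground truth.
"""

from __future__ import annotations

import numpy as np

from .channels import BASES, CLASSES
from .types import Spectrum96

_UNIFORM = {b: 0.25 for b in BASES}

# class weight, 5' flank weights, 3' flank weights (normalised per class)
_SPECTRA: dict[str, dict[str, tuple[float, dict, dict]]] = {
    "mock": {
        "C>T": (0.38, _UNIFORM, {"A": 0.13, "C": 0.13, "G": 0.61, "T": 0.13}),
        "C>A": (0.25, _UNIFORM, _UNIFORM),
        "T>C": (0.12, _UNIFORM, _UNIFORM),
        "T>A": (0.09, _UNIFORM, _UNIFORM),
        "C>G": (0.08, _UNIFORM, _UNIFORM),
        "T>G": (0.08, _UNIFORM, _UNIFORM),
    },
    "cisplatin": {
        # 3' flank of C>A: C 0.40/0.57, T 0.12/0.57, remainder split on A/G
        "C>A": (0.57, _UNIFORM, {"A": 0.053, "C": 0.702, "G": 0.035, "T": 0.210}),
        "T>A": (0.13, {"A": 0.14, "C": 0.50, "G": 0.14, "T": 0.22},
                {"A": 0.10, "C": 0.70, "G": 0.10, "T": 0.10}),
        "C>T": (0.12, _UNIFORM, _UNIFORM),
        "T>C": (0.08, _UNIFORM, _UNIFORM),
        "C>G": (0.05, _UNIFORM, _UNIFORM),
        "T>G": (0.05, _UNIFORM, _UNIFORM),
    },
    "cyclophosphamide": {
        "T>A": (0.35, {"A": 0.15, "C": 0.35, "G": 0.15, "T": 0.35},
                {"A": 0.10, "C": 0.10, "G": 0.10, "T": 0.70}),
        "C>T": (0.30, _UNIFORM, _UNIFORM),
        "T>C": (0.12, _UNIFORM, {"A": 0.17, "C": 0.17, "G": 0.16, "T": 0.50}),
        "T>G": (0.10, _UNIFORM, {"A": 0.17, "C": 0.17, "G": 0.16, "T": 0.50}),
        "C>A": (0.08, _UNIFORM, _UNIFORM),
        "C>G": (0.05, _UNIFORM, _UNIFORM),
    },
}

# insertion patterns: (preceding 2 bases, inserted base, following 2 bases),
# N = any base; placed on either strand with equal probability.
_INSERTION_MODELS: dict[str, dict[tuple[str, str, str], float]] = {
    "mock": {
        ("NN", "T", "NN"): 0.5,
        ("NN", "C", "NN"): 0.5,
    },
    "cisplatin": {
        ("GG", "T", "TN"): 0.45,
        ("GG", "T", "NN"): 0.25,
        ("NN", "T", "TN"): 0.14,
        ("NN", "T", "NN"): 0.10,
        ("CC", "C", "NN"): 0.04,
        ("NN", "C", "NN"): 0.02,
    },
}
_INSERTION_MODELS["cyclophosphamide"] = _INSERTION_MODELS["mock"]

# deletion patterns: (preceding base, deleted sequence, following base)
_DELETION_MODELS: dict[str, dict[tuple[str, str, str], float]] = {
    "mock": {
        ("N", "T", "N"): 0.5,
        ("N", "C", "N"): 0.5,
    },
    "cisplatin": {
        ("A", "G", "C"): 0.20,
        ("C", "A", "G"): 0.12,
        ("G", "G", "N"): 0.20,
        ("N", "G", "G"): 0.10,
        ("N", "T", "N"): 0.08,
        ("N", "AG", "N"): 0.15,
        ("N", "GG", "N"): 0.08,
        ("N", "TG", "N"): 0.04,
        ("N", "CA", "N"): 0.03,
    },
}
_DELETION_MODELS["cyclophosphamide"] = _DELETION_MODELS["mock"]

#: fraction of SNV draws emitted as adjacent dinucleotide pairs
_DNV_FRACTIONS = {"mock": 0.0, "cisplatin": 0.08, "cyclophosphamide": 0.0}

#: per-clone Poisson means (n_snv, n_ins, n_del), scaled-down study-like ratios
_EVENT_MEANS = {
    "mock": (47.0, 4.5, 3.0),
    "cisplatin": (200.0, 12.0, 20.0),
    "cyclophosphamide": (200.0, 3.0, 5.0),
}

PRESET_NAMES = tuple(sorted(_SPECTRA))


def preset_spectrum(name: str) -> Spectrum96:
    """The 96-channel probability vector of a named preset (sums to 1)."""
    try:
        spec = _SPECTRA[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}") from None
    values = np.zeros(96)
    for i, cls in enumerate(CLASSES):
        if cls not in spec:
            continue
        weight, w5, w3 = spec[cls]
        block = np.array([[w5[f] * w3[t] for t in BASES] for f in BASES])
        block = weight * block / block.sum()
        values[i * 16: (i + 1) * 16] = block.ravel()
    return Spectrum96(values / values.sum())


def preset_indel_models(name: str) -> tuple[dict, dict]:
    """(insertion_model, deletion_model) pattern-weight dicts of a preset."""
    if name not in _SPECTRA:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return dict(_INSERTION_MODELS[name]), dict(_DELETION_MODELS[name])


def preset_sim_config(name: str, **overrides):
    """A ready-to-run :class:`~clonemut.simulate.SimConfig` for a preset."""
    from .simulate import SimConfig

    ins_model, del_model = preset_indel_models(name)
    n_snv, n_ins, n_del = _EVENT_MEANS[name]
    kwargs = dict(
        spectrum_weights=preset_spectrum(name).values,
        insertion_model=ins_model,
        deletion_model=del_model,
        dnv_fraction=_DNV_FRACTIONS[name],
        n_snv=n_snv,
        n_ins=n_ins,
        n_del=n_del,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)
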