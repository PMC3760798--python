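"""Parameters of the IKK–IκB–NF-κB signalling module.

The model tracks one NF-κB species (RelA-containing dimers, lumped) shuttling
between cytoplasm and nucleus, three IκB isoforms (α, β, ε) as free protein,
NF-κB-bound complex and mRNA, and takes IKK kinase activity as an external,
numerically defined input.  Units throughout: concentrations in µM
(cytoplasm-referenced where volume-weighted), time in minutes, IKK activity as a
dimensionless fraction of its maximum.

The shipped default parameter set follows the published precursor model family
for this module (``provenance = precursor_default``); the adaptation applied on
top of it — IκB mRNA degradation increased 1.8-fold and additive
(basal + saturable induced) transcription terms for IκBα and IκBε — is performed
by :func:`apply_model_adaptations` and recorded in the ``modified`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

ISOFORMS = ("a", "b", "e")

#: factor by which IκB mRNA degradation rates are increased in the adapted model
MRNA_DEGRADATION_FACTOR = 1.8


@dataclass(frozen=True)
class TranscriptionTerm:
    """Additive Pol-II-recruitment transcription term.

    Production rate at nuclear NF-κB concentration ``N`` is

        k_basal + k_induced_max * (N/K_half)**h / (1 + (N/K_half)**h)

    so the rate equals ``k_basal`` at N = 0, rises saturably, and is bounded by
    ``k_basal + k_induced_max``.

    Parameters
    ----------
    k_basal : float
        Constitutive mRNA production rate (µM/min).
    k_induced_max : float
        Maximal NF-κB-dependent production rate (µM/min).
    K_half : float
        Nuclear NF-κB concentration at half-maximal induced production (µM).
    h : float
        Hill coefficient (dimensionless, default 1).
    """

    k_basal: float
    k_induced_max: float
    K_half: float
    h: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_basal", "k_induced_max", "K_half", "h"):
            if getattr(self, name) < 0:
                raise ValueError(f"TranscriptionTerm.{name} must be >= 0")

    def rate(self, nuclear_nfkb: float, induced_scale: float = 1.0) -> float:
        """Production rate at the given nuclear NF-κB concentration.

        ``induced_scale`` multiplies only the NF-κB-dependent term (this is the
        k_mRNA suppression knob; it never touches ``k_basal``).
        """
        n = np.maximum(np.asarray(nuclear_nfkb, dtype=float), 0.0)
        if self.k_induced_max == 0.0:
            return self.k_basal + 0.0 * n
        x = (n / self.K_half) ** self.h
        return self.k_basal + induced_scale * self.k_induced_max * x / (1.0 + x)


def _iso_map(values: Mapping[str, float]) -> dict[str, float]:
    if set(values) != set(ISOFORMS):
        raise ValueError(f"expected one value per isoform {ISOFORMS}, got {set(values)}")
    return {k: float(values[k]) for k in ISOFORMS}


@dataclass(frozen=True)
class ModelParameters:
    """Full parameterization of the feedback module.

    Per-isoform fields are mappings keyed ``'a'``, ``'b'``, ``'e'`` (IκBα, β, ε).
    Degradation rates tagged ``ikk`` are multiplied by the instantaneous IKK
    activity fraction; ``basal`` rates act unconditionally.
    """

    transcription: Mapping[str, TranscriptionTerm]
    translation_rate: Mapping[str, float]          # 1/min, per mRNA
    mrna_degradation: Mapping[str, float]          # 1/min
    deg_free_basal: Mapping[str, float]            # 1/min, free IκB
    deg_free_ikk: Mapping[str, float]              # 1/min at IKK activity 1
    deg_bound_basal: Mapping[str, float]           # 1/min, NF-κB-bound IκB
    deg_bound_ikk: Mapping[str, float]             # 1/min at IKK activity 1
    assoc: Mapping[str, float]                     # 1/(µM·min)
    dissoc: Mapping[str, float]                    # 1/min
    ikb_import: Mapping[str, float]                # 1/min, free IκB nuclear import
    ikb_export: Mapping[str, float]                # 1/min, free nuclear IκB export
    complex_export: Mapping[str, float]            # 1/min, nuclear IκB:NF-κB export
    nfkb_import: float                             # 1/min
    nfkb_export: float                             # 1/min
    volume_ratio: float                            # cytoplasmic:nuclear volume
    total_nfkb: float                              # µM, cytoplasm-referenced
    nfkb_scale: float = 1.0                        # abundance-scan multiplier
    kmrna_scale: float = 1.0                       # IκBα induced-term multiplier
    mrna_degradation_factor: float = MRNA_DEGRADATION_FACTOR
    modified: bool = False                         # adaptation applied exactly once
    provenance: str = "precursor_default"

    def __post_init__(self) -> None:
        for name in ("translation_rate", "mrna_degradation", "deg_free_basal",
                     "deg_free_ikk", "deg_bound_basal", "deg_bound_ikk",
                     "assoc", "dissoc", "ikb_import", "ikb_export",
                     "complex_export"):
            m = _iso_map(getattr(self, name))
            object.__setattr__(self, name, m)
            if any(v < 0 for v in m.values()):
                raise ValueError(f"ModelParameters.{name} must be >= 0")
        if set(self.transcription) != set(ISOFORMS):
            raise ValueError("transcription needs one term per isoform")
        for v, name in ((self.nfkb_import, "nfkb_import"),
                        (self.nfkb_export, "nfkb_export"),
                        (self.total_nfkb, "total_nfkb")):
            if v < 0:
                raise ValueError(f"ModelParameters.{name} must be >= 0")
        if self.volume_ratio <= 0:
            raise ValueError("volume_ratio must be > 0")
        if self.nfkb_scale <= 0:
            raise ValueError("nfkb_scale must be > 0")
        if not (0 < self.kmrna_scale <= 1):
            raise ValueError("kmrna_scale must lie in (0, 1]")

    @property
    def effective_total_nfkb(self) -> float:
        """Volume-weighted total NF-κB after abundance scaling (µM)."""
        return self.total_nfkb * self.nfkb_scale

    def with_scales(self, nfkb_scale: float | None = None,
                    kmrna_scale: float | None = None) -> "ModelParameters":
        kw = {}
        if nfkb_scale is not None:
            kw["nfkb_scale"] = nfkb_scale
        if kmrna_scale is not None:
            kw["kmrna_scale"] = kmrna_scale
        return replace(self, **kw)


def apply_model_adaptations(base: ModelParameters) -> ModelParameters:
    """Apply the adaptation of the precursor model.

    Multiplies every IκB mRNA degradation rate by ``mrna_degradation_factor``
    (1.8, in line with direct mRNA half-life measurements) and stamps the
    parameters as carrying the additive (basal + saturable induced)
    transcription terms for IκBα and IκBε.  IκBβ is not NF-κB-inducible
    (``k_induced_max`` must be 0).

    Raises
    ------
    ValueError
        If the modification flag is already set (double application would
        compound the 1.8 factor).
    """
    if base.modified:
        raise ValueError("model adaptations already applied (modified flag set)")
    if base.transcription["b"].k_induced_max != 0:
        raise ValueError("IκBβ transcription must be constitutive (k_induced_max = 0)")
    new_deg = {k: v * base.mrna_degradation_factor
               for k, v in base.mrna_degradation.items()}
    return replace(base, mrna_degradation=new_deg, modified=True)


# ---------------------------------------------------------------------------
# parameter file I/O: flat key-value table, keys one-to-one with the fields
# ---------------------------------------------------------------------------

_ISO_FIELDS = ("translation_rate", "mrna_degradation", "deg_free_basal",
               "deg_free_ikk", "deg_bound_basal", "deg_bound_ikk", "assoc",
               "dissoc", "ikb_import", "ikb_export", "complex_export")
_SCALAR_FIELDS = ("nfkb_import", "nfkb_export", "volume_ratio", "total_nfkb",
                  "nfkb_scale", "kmrna_scale", "mrna_degradation_factor")
_TX_FIELDS = ("k_basal", "k_induced_max", "K_half", "h")


def load_parameters(path: str | Path) -> ModelParameters:
    """Read a flat ``key<TAB>value`` parameter file.

    Per-isoform keys are suffixed ``_a``, ``_b``, ``_e``; transcription keys are
    ``tx_<field>_<iso>``.  ``provenance`` and ``modified`` are optional string
    keys; everything else is numeric.
    """
    kv: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("\t") if "\t" in line else line.partition("=")
        kv[key.strip()] = val.strip()

    def num(key: str) -> float:
        if key not in kv:
            raise KeyError(f"parameter file missing key {key!r}")
        return float(kv.pop(key))

    tx = {iso: TranscriptionTerm(**{f: num(f"tx_{f}_{iso}") for f in _TX_FIELDS})
          for iso in ISOFORMS}
    iso_kw = {name: {iso: num(f"{name}_{iso}") for iso in ISOFORMS}
              for name in _ISO_FIELDS}
    scal_kw = {name: num(name) for name in _SCALAR_FIELDS}
    provenance = kv.pop("provenance", "precursor_default")
    modified = kv.pop("modified", "false").lower() in ("true", "1", "yes")
    if kv:
        raise ValueError(f"unrecognized parameter keys: {sorted(kv)}")
    return ModelParameters(transcription=tx, **iso_kw, **scal_kw,
                           provenance=provenance, modified=modified)


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    lines = [f"# model parameter file (units: µM, min)",
             f"provenance\t{params.provenance}",
             f"modified\t{str(params.modified).lower()}"]
    for iso in ISOFORMS:
        t = params.transcription[iso]
        for f in _TX_FIELDS:
            lines.append(f"tx_{f}_{iso}\t{float(getattr(t, f))!r}")
    for name in _ISO_FIELDS:
        for iso in ISOFORMS:
            lines.append(f"{name}_{iso}\t{float(getattr(params, name)[iso])!r}")
    for name in _SCALAR_FIELDS:
        lines.append(f"{name}\t{float(getattr(params, name))!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def default_parameters(modified: bool = True) -> ModelParameters:
    """Shipped default parameter set.

    Reconstructed from the precursor model family for this signalling module
    (flagged ``provenance = precursor_default``).  With ``modified=True``
    (default) the adaptation of :func:`apply_model_adaptations` is applied,
    which is the state every simulation entry point expects.
    """
    with resources.as_file(resources.files("relacbp.data") / "params_precursor.tsv") as p:
        base = load_parameters(p)
    return apply_model_adaptations(base) if modified else base
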