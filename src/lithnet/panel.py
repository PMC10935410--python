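"""The 28-analyte intracellular protein panel.

Each analyte is one antibody-defined measurement target in CD4+ lymphocytes
and monocytes: a protein or a specific phospho-form, so several analytes may
later collapse onto one gene (see :mod:`lithnet.network`).  ``DEFAULT_PANEL``
lists the analytes in the order used for correlation-grid output, with the
functional category of each target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .errors import ValidationError

__all__ = ["AnalytePanel", "DEFAULT_PANEL", "DEFAULT_ANCHORS"]


@dataclass(frozen=True)
class AnalytePanel:
    """An ordered panel of analyte names with functional categories."""

    analytes: tuple[str, ...]
    categories: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.analytes)) != len(self.analytes):
            raise ValidationError("analyte names must be unique")
        extra = set(self.categories) - set(self.analytes)
        if extra:
            raise ValidationError(f"categories for unknown analytes: {sorted(extra)}")

    def __contains__(self, analyte: str) -> bool:
        return analyte in self.analytes

    def __iter__(self) -> Iterator[str]:
        return iter(self.analytes)

    def __len__(self) -> int:
        return len(self.analytes)

    def index(self, analyte: str) -> int:
        return self.analytes.index(analyte)

    def category(self, analyte: str) -> str:
        return self.categories.get(analyte, "unknown")


# Grid display order for the 28-analyte panel.
_ANALYTES = (
    "NLRP3",
    "PDEB4",
    "BAX",
    "phospho-Fyn/phospho-Yes",
    "HMGB1",
    "BCL-2 A1",
    "BDNF",
    "GSK3β",
    "XBP1",
    "MARCKS",
    "phospho-GSK3β",
    "phospho-GSK3α/β",
    "Fyn",
    "Timeless",
    "PGM1",
    "phospho-NFkB-P65",
    "CALM1",
    "IRS2",
    "phospho-CREB",
    "PPAR-γ",
    "TNFAIP3",
    "TPH1",
    "PKC-θ",
    "BCL-2",
    "iNOS",
    "NR3C1",
    "mTor",
    "PKA C-α",
)

_CATEGORIES = {
    "BAX": "apoptosis",
    "BCL-2": "apoptosis",
    "BCL-2 A1": "apoptosis",
    "CALM1": "calcium transport",
    "GSK3β": "cell signaling",
    "phospho-GSK3α/β": "cell signaling",
    "phospho-GSK3β": "cell signaling",
    "iNOS": "cell signaling",
    "PDEB4": "cell signaling",
    "Timeless": "circadian rhythm",
    "PGM1": "metabolic enzyme",
    "TPH1": "metabolic enzyme",
    "HMGB1": "inflammation",
    "NLRP3": "inflammation",
    "TNFAIP3": "inflammation",
    "MARCKS": "inflammation",
    "Fyn": "kinase",
    "phospho-Fyn/phospho-Yes": "kinase",
    "PKA C-α": "kinase",
    "PKC-θ": "kinase",
    "mTor": "kinase",
    "BDNF": "neurotrophic factor",
    "IRS2": "receptor",
    "PPAR-γ": "receptor",
    "NR3C1": "receptor",
    "phospho-NFkB-P65": "transcription factor",
    "phospho-CREB": "transcription factor",
    "XBP1": "transcription factor",
}

DEFAULT_PANEL = AnalytePanel(analytes=_ANALYTES, categories=_CATEGORIES)

#: Anchor analytes whose correlation with every other analyte is profiled
#: before and after treatment.
DEFAULT_ANCHORS = ("GSK3β", "PDEB4", "NLRP3")
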