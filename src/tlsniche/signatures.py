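"""Gene signatures: the named gene lists driving scoring and region calling.

A :class:`SignatureSet` is a named, role-tagged gene list. The registry below
ships the lists that are printed in full in the study's methods (region
markers, pan-Ig, plasma-spot, EBV genes, immunosuppressive genes); longer
curated lists (top-100 DEG signatures, apoptosis modules, the germinal-centre
gene panel) are runtime inputs supplied as GMT or JSON files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "SignatureSet",
    "REGISTRY",
    "TLS_SIGNATURE_NAMES",
    "read_gmt",
    "write_gmt",
    "read_json_signatures",
]


@dataclass(frozen=True)
class SignatureSet:
    """A named gene list with a role tag.

    Parameters
    ----------
    name : str
        Signature identifier, e.g. ``"pan_Ig"``.
    genes : tuple of str
        Unique, non-empty gene list.
    role : str
        Free-form role tag (``"malignant"``, ``"B"``, ``"T"``, ``"EBV"``,
        ``"plasma"``, ``"pan_Ig"``, ``"apoptosis"``, ``"immunosuppressive"``,
        ``"TLS"`` ...). Used by callers to select signatures by function.
    """

    name: str
    genes: tuple[str, ...]
    role: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"signature {self.name!r} has an empty gene list")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def intersect(self, universe: Iterable[str]) -> tuple[str, ...]:
        """Genes of this set present in `universe`, in signature order."""
        u = set(universe)
        return tuple(g for g in self.genes if g in u)


def _sig(name: str, role: str, genes: Iterable[str]) -> SignatureSet:
    return SignatureSet(name=name, genes=tuple(genes), role=role)


#: Malignant / B / T markers used to call TCA and TLS regions.
MALIGNANT_MARKERS = _sig("malignant_markers", "malignant",
                         ["EPCAM", "KRT13", "KRT8", "KRT5"])
B_CELL_MARKERS = _sig("B_cell_markers", "B",
                      ["CD19", "MS4A1", "CD79A", "CD79B"])
T_CELL_MARKERS = _sig("T_cell_markers", "T",
                      ["CD2", "CD3D", "CD3E", "CD3G", "CD7"])

#: Summed immunoglobulin heavy-chain transcripts, an antibody-production proxy.
PAN_IG = _sig("pan_Ig", "pan_Ig",
              ["IGHA1", "IGHA2", "IGHG1", "IGHG2", "IGHG3", "IGHG4"])

#: Plasma-cell-occupied spot signature (B-lineage plasma markers + pan-Ig).
PLASMA_SPOT = _sig("plasma_spot", "plasma",
                   ["CD79A", "CD79B", "MZB1", "XBP1",
                    "IGHA1", "IGHA2", "IGHG1", "IGHG2", "IGHG3", "IGHG4"])

#: EBV-encoded transcripts captured by fresh-frozen platforms.
EBV_GENES = _sig("EBV_genes", "EBV",
                 ["RPMS1", "A73", "BARF0", "BALF3", "BALF4",
                  "LMP1", "BNLF2A", "BNLF2B", "LMP2A", "LMP2B",
                  "EBNA1", "EBNA2", "EBNA3A", "EBNA3B", "EBNA3C", "EBNALP"])

#: Immunosuppressive ligand/checkpoint gene panel.
IMMUNOSUPPRESSIVE = _sig("immunosuppressive", "immunosuppressive",
                         ["CD47", "PVR", "CD276", "LGALS9", "ADORA2B",
                          "ADAM10", "HLA-G", "CD274", "FASLG", "TGFB1", "IL10"])

#: The seven TLS-associated cell-cluster signatures whose joint score (TLS-CS)
#: stratifies patients. The gene lists themselves are derived from data
#: (top-100 DEGs per cluster) and must be registered at run time.
TLS_SIGNATURE_NAMES: tuple[str, ...] = (
    "Naive_B", "Memory_B", "GC_B", "Plasma",
    "CD4_C8_CXCR5", "CD8_C8_CXCL13", "iCAF_C2_CXCL13",
)

REGISTRY: dict[str, SignatureSet] = {
    s.name: s
    for s in (
        MALIGNANT_MARKERS, B_CELL_MARKERS, T_CELL_MARKERS,
        PAN_IG, PLASMA_SPOT, EBV_GENES, IMMUNOSUPPRESSIVE,
    )
}


# ---------------------------------------------------------------------------
# IO: GMT and JSON signature collections
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, role: str = "") -> dict[str, SignatureSet]:
    """Read a GMT file (name <tab> description <tab> genes...) into sets."""
    sets: dict[str, SignatureSet] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        name, _desc, *genes = fields
        genes = [g for g in genes if g]
        # preserve order, drop duplicates
        seen: dict[str, None] = dict.fromkeys(genes)
        sets[name] = SignatureSet(name=name, genes=tuple(seen), role=role)
    return sets


def write_gmt(sets: Mapping[str, SignatureSet], path: str | Path) -> None:
    lines = [
        "\t".join([s.name, s.role or "na", *s.genes]) for s in sets.values()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_json_signatures(path: str | Path) -> dict[str, SignatureSet]:
    """Read ``{"name": {"role": ..., "genes": [...]}}`` or ``{"name": [...]}``."""
    raw = json.loads(Path(path).read_text())
    sets: dict[str, SignatureSet] = {}
    for name, val in raw.items():
        if isinstance(val, dict):
            sets[name] = SignatureSet(name=name, genes=tuple(val["genes"]),
                                      role=val.get("role", ""))
        else:
            sets[name] = SignatureSet(name=name, genes=tuple(val))
    return sets
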