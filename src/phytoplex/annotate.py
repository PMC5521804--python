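"""Fragmentation-based annotation of negative-mode LC-MS/MS spectra.

Two rule families used for putative metabolite annotation:

* glycoside neutral losses — a parent→fragment mass difference of 132, 146
  or 162 Da marks the departure of a pentose, deoxyhexose or hexose sugar;
* hydroxycinnamic-acid diagnostic chains — an MS² fragment with a specific
  MS³ child identifies the acyl class: 179→135 caffeic, 163→119 coumaric,
  191→173 quinic, and 193→134/149/178 ferulic derivatives.

Masses are matched within a tolerance (default 0.5 Da, unit resolution);
losses are evaluated on every parent→child edge of the fragment tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "FragmentNode",
    "FragmentTree",
    "NeutralLoss",
    "HCAAnnotation",
    "NEUTRAL_LOSSES",
    "HCA_SIGNATURES",
    "detect_neutral_losses",
    "annotate_hca_class",
]

DEFAULT_TOLERANCE = 0.5

#: diagnostic neutral losses (monoisotopic Da) of glycosyl moieties
NEUTRAL_LOSSES: dict[str, float] = {
    "pentose": 132.0423,
    "deoxyhexose": 146.0579,
    "hexose": 162.0528,
}

#: MS2 fragment -> (MS3 children, class) signature chains
HCA_SIGNATURES: dict[str, tuple[float, tuple[float, ...]]] = {
    "caffeic": (179.0, (135.0,)),
    "coumaric": (163.0, (119.0,)),
    "quinic": (191.0, (173.0,)),
    "ferulic": (193.0, (134.0, 149.0, 178.0)),
}


@dataclass(frozen=True)
class FragmentNode:
    level: str  # "MS2" | "MS3"
    parent_mz: float
    fragment_mz: float

    def __post_init__(self) -> None:
        if self.level not in ("MS2", "MS3"):
            raise ValueError(f"level must be MS2 or MS3, got {self.level!r}")
        if self.parent_mz <= 0 or self.fragment_mz <= 0:
            raise ValueError("m/z values must be positive")


@dataclass
class FragmentTree:
    """Precursor with its MS² fragments and their MS³ children.

    Every MS³ node's parent must appear as an MS² fragment (within
    tolerance); violating nodes are rejected at construction.
    """

    precursor_mz: float
    nodes: list[FragmentNode] = field(default_factory=list)
    tolerance: float = DEFAULT_TOLERANCE

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        ms2 = [n.fragment_mz for n in self.nodes if n.level == "MS2"]
        for node in self.nodes:
            if node.level == "MS3" and not any(
                abs(node.parent_mz - f) <= self.tolerance for f in ms2
            ):
                raise ValueError(
                    f"MS3 node parent {node.parent_mz} matches no MS2 fragment"
                )

    def edges(self) -> list[tuple[float, float]]:
        """All parent→child (m/z, m/z) pairs, precursor edges included."""
        return [(n.parent_mz, n.fragment_mz) for n in self.nodes]

    def ms2_fragments(self) -> list[float]:
        return [n.fragment_mz for n in self.nodes if n.level == "MS2"]

    def ms3_children(self, parent_mz: float, tolerance: float) -> list[float]:
        return [
            n.fragment_mz
            for n in self.nodes
            if n.level == "MS3" and abs(n.parent_mz - parent_mz) <= tolerance
        ]

    @classmethod
    def from_table(cls, table: pd.DataFrame, tolerance: float = DEFAULT_TOLERANCE) -> "FragmentTree":
        """Build from a long table with columns precursor_mz, level,
        parent_mz, fragment_mz (one precursor per table)."""
        precursors = table["precursor_mz"].unique()
        if len(precursors) != 1:
            raise ValueError("fragment table must describe a single precursor")
        nodes = [
            FragmentNode(str(r.level), float(r.parent_mz), float(r.fragment_mz))
            for r in table.itertuples(index=False)
        ]
        return cls(float(precursors[0]), nodes, tolerance)


@dataclass(frozen=True)
class NeutralLoss:
    loss_type: str
    parent_mz: float
    fragment_mz: float
    delta: float


def detect_neutral_losses(
    tree: FragmentTree, tolerance: float | None = None
) -> list[NeutralLoss]:
    """Label every parent→fragment delta matching a glycosyl neutral loss."""
    tol = tree.tolerance if tolerance is None else tolerance
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    hits = []
    for parent, fragment in tree.edges():
        delta = parent - fragment
        for name, loss in NEUTRAL_LOSSES.items():
            if abs(delta - loss) <= tol:
                hits.append(NeutralLoss(name, parent, fragment, delta))
    return hits


@dataclass
class HCAAnnotation:
    """Hydroxycinnamic-acid class call; ``classes`` empty means no match."""

    classes: list[str]

    @property
    def multiple(self) -> bool:
        return len(self.classes) > 1

    @property
    def label(self) -> str:
        return "none" if not self.classes else "+".join(self.classes)


def annotate_hca_class(
    tree: FragmentTree,
    tolerance: float | None = None,
    ferulic_children: str = "any",
) -> HCAAnnotation:
    """Match the diagnostic MS²→MS³ chains of hydroxycinnamic-acid classes.

    A class matches when the tree holds an MS² fragment at the signature
    m/z with the required MS³ child; for ferulic derivatives, ``any`` (the
    default) of 134/149/178 suffices, or ``all`` to demand every child.
    Multiple matching classes are all returned (``multiple`` flag).
    """
    tol = tree.tolerance if tolerance is None else tolerance
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if ferulic_children not in ("any", "all"):
        raise ValueError("ferulic_children must be 'any' or 'all'")
    matches = []
    for cls, (ms2_mz, children) in HCA_SIGNATURES.items():
        for frag in tree.ms2_fragments():
            if abs(frag - ms2_mz) > tol:
                continue
            kids = tree.ms3_children(frag, tol)
            found = [
                any(abs(k - child) <= tol for k in kids) for child in children
            ]
            need_all = cls == "ferulic" and ferulic_children == "all"
            if (all(found) if need_all else any(found)):
                matches.append(cls)
                break
    return HCAAnnotation(classes=matches)
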