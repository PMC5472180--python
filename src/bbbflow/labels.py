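"""Integer label codes for the tissue compartments.

One closed vocabulary is used everywhere: the synthetic anatomy, the merged
tissue map, the contour map and the long slope table all speak these names.
Contours are numbered 1 (adjacent to the WMH edge) to ``n`` (furthest out);
NAWM beyond the last contour is ``distant-NAWM``.
"""

from __future__ import annotations

BACKGROUND = 0
CSF = 1
NAWM = 2  # distant NAWM once contours are drawn; whole NAWM before
DGM = 3
WMH_LESS = 4
WMH_INTENSE = 5
INDEX_INFARCT = 6
OLD_INFARCT = 7
SINUS = 8
CONTOUR_BASE = 10  # contour k -> CONTOUR_BASE + k

LABEL_NAMES: dict[int, str] = {
    BACKGROUND: "background",
    CSF: "csf",
    NAWM: "nawm",
    DGM: "dgm",
    WMH_LESS: "wmh_less_intense",
    WMH_INTENSE: "wmh_intense",
    INDEX_INFARCT: "index_infarct",
    OLD_INFARCT: "old_infarct",
    SINUS: "sinus",
}


def contour_label(k: int) -> int:
    """Label code of contour ``k`` (1-based, 1 = nearest the WMH edge)."""
    if k < 1:
        raise ValueError(f"contour index must be >= 1, got {k}")
    return CONTOUR_BASE + k


def contour_name(k: int) -> str:
    return f"contour_{k}"


def label_name(code: int) -> str:
    if code in LABEL_NAMES:
        return LABEL_NAMES[code]
    if code > CONTOUR_BASE:
        return contour_name(code - CONTOUR_BASE)
    raise KeyError(f"unknown label code {code}")


def name_to_label(name: str) -> int:
    for code, nm in LABEL_NAMES.items():
        if nm == name:
            return code
    if name.startswith("contour_"):
        return contour_label(int(name.split("_")[1]))
    raise KeyError(f"unknown label name {name!r}")


#: tissue strata used by the headline leakage models (WMH pooled, as printed)
MODEL_TISSUES = ("nawm", "dgm", "csf", "wmh", "index_infarct", "old_infarct")
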