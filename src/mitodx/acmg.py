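"""Five-class variant classification from weighted ACMG evidence codes.

The engine combines evidence codes (PVS/PS/PM/PP on the pathogenic side,
BA/BS/BP on the benign side) into one of pathogenic, likely_pathogenic,
vus, likely_benign or benign using the standard 2015 combining rules.
Codes may carry a strength modifier (e.g. PM3 upgraded to strong) and
participate in the rules at their modified strength.  The engine takes
codes as input; it does not derive them from annotations.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Optional

PATHOGENIC_CODES = frozenset(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
)
BENIGN_CODES = frozenset(["BA1"] + [f"BS{i}" for i in range(1, 5)] + [f"BP{i}" for i in range(1, 8)])
ALL_CODES = PATHOGENIC_CODES | BENIGN_CODES

STRENGTHS = {"very_strong", "strong", "moderate", "supporting", "stand_alone"}

#: intrinsic strength of each code prefix
_INTRINSIC = {
    "PVS": "very_strong",
    "PS": "strong",
    "PM": "moderate",
    "PP": "supporting",
    "BA": "stand_alone",
    "BS": "strong",
    "BP": "supporting",
}


def _prefix(code: str) -> str:
    return code[:3] if code.startswith(("PVS", "BA1")) else code[:2]


def intrinsic_strength(code: str) -> str:
    for pre, s in _INTRINSIC.items():
        if code.startswith(pre):
            return s
    raise ValueError(f"unknown ACMG code {code!r}")


def _tally(
    codes: Iterable[tuple[str, Optional[str]]]
) -> tuple[Counter, Counter, bool]:
    """Count pathogenic- and benign-side codes by effective strength."""
    pato: Counter = Counter()
    beni: Counter = Counter()
    ba1 = False
    seen: set[str] = set()
    for code, modifier in codes:
        if code not in ALL_CODES:
            raise ValueError(f"unknown ACMG code {code!r}")
        if code in seen:
            raise ValueError(f"ACMG code {code} given more than once")
        seen.add(code)
        strength = modifier or intrinsic_strength(code)
        if strength not in STRENGTHS:
            raise ValueError(f"unknown strength modifier {strength!r}")
        if code == "BA1":
            ba1 = True
        elif code in PATHOGENIC_CODES:
            pato[strength] += 1
        else:
            beni[strength] += 1
    return pato, beni, ba1


def _pathogenic_side(p: Counter) -> Optional[str]:
    """Class reached by the pathogenic-side rule rows, if any."""
    vs = p["very_strong"]
    st = p["strong"]
    mo = p["moderate"]
    su = p["supporting"]
    pathogenic = (
        (vs >= 1 and (st >= 1 or mo >= 2 or (mo >= 1 and su >= 1) or su >= 2))
        or vs >= 2
        or st >= 2
        or (st == 1 and (mo >= 3 or (mo >= 2 and su >= 2) or (mo >= 1 and su >= 4)))
    )
    if pathogenic:
        return "pathogenic"
    likely = (
        (vs >= 1 and mo >= 1)
        or (st == 1 and 1 <= mo <= 2)
        or (st == 1 and su >= 2)
        or mo >= 3
        or (mo == 2 and su >= 2)
        or (mo == 1 and su >= 4)
    )
    if likely:
        return "likely_pathogenic"
    return None


def _benign_side(b: Counter, ba1: bool) -> Optional[str]:
    if ba1 or b["strong"] >= 2:
        return "benign"
    if (b["strong"] >= 1 and b["supporting"] >= 1) or b["supporting"] >= 2:
        return "likely_benign"
    return None


def combine_evidence(codes: Iterable[tuple[str, Optional[str]]]) -> str:
    """Combine ACMG evidence codes into a five-class call.

    Parameters
    ----------
    codes
        ``(code, modifier)`` pairs; ``modifier`` is ``None`` for the
        code's intrinsic strength or one of ``very_strong``, ``strong``,
        ``moderate``, ``supporting``.

    Returns
    -------
    str
        One of ``pathogenic``, ``likely_pathogenic``, ``vus``,
        ``likely_benign``, ``benign``.  When both a pathogenic-side and a
        benign-side rule row are satisfied the evidence is contradictory
        and the call clamps to ``vus``.
    """
    pato, beni, ba1 = _tally(codes)
    p_class = _pathogenic_side(pato)
    b_class = _benign_side(beni, ba1)
    if p_class and b_class:
        return "vus"
    return p_class or b_class or "vus"


def classify_evidence_map(
    evidence: dict[str, list[tuple[str, Optional[str]]]]
) -> dict[str, str]:
    """Classify every variant key present in an evidence table."""
    return {key: combine_evidence(ev) for key, ev in evidence.items()}
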