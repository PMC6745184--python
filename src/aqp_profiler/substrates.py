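"""Substrate-specificity rules over the nine SDP residues.

Each of the six non-aqua substrates (ammonia, boric acid, CO2, H2O2,
silicic acid, urea) is defined by nine allowed-residue sets, one per
specificity-determining position.  A protein whose nine residues all fall
in the allowed sets is a member of the substrate class; exactly one
substitution marks a *novel-site* member (a known transporter type with a
single new residue); two or more mismatches exclude it.  Unresolved
positions (alignment gaps) count as mismatches but are reported
distinctly so the call stays auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .features import FeatureProfile, UNRESOLVED

SUBSTRATES = ("ammonia", "boric_acid", "co2", "h2o2", "silicic_acid", "urea")

MEMBER = "member"
MEMBER_NOVEL = "member_novel"
NON_MEMBER = "non_member"


@dataclass(frozen=True)
class SubstratePattern:
    """Nine ordered allowed-residue sets for one substrate class."""

    substrate: str
    allowed: tuple[frozenset[str], ...]

    def __post_init__(self):
        if len(self.allowed) != 9:
            raise ValueError(f"{self.substrate}: need exactly 9 residue sets")
        if any(not s for s in self.allowed):
            raise ValueError(f"{self.substrate}: empty allowed set")


@dataclass(frozen=True)
class SubstrateCall:
    query_id: str
    substrate: str
    status: str
    mismatch_positions: tuple[int, ...] = ()  # 1-based SDP indices
    novel_residues: tuple[tuple[int, str], ...] = ()
    unresolved_positions: tuple[int, ...] = ()


def _data_text(name: str) -> str:
    return resources.files("aqp_profiler.data").joinpath(name).read_text()


def builtin_patterns() -> list[SubstratePattern]:
    """The six published substrate patterns, shipped as a data file.

    One row per substrate, nine slash-delimited residue sets.
    """
    from io import StringIO

    df = pd.read_csv(StringIO(_data_text("substrate_patterns.tsv")), sep="\t")
    patterns = []
    for _, row in df.iterrows():
        allowed = tuple(frozenset(row[f"SDP{i}"].split("/")) for i in range(1, 10))
        patterns.append(SubstratePattern(substrate=row["substrate"], allowed=allowed))
    if {p.substrate for p in patterns} != set(SUBSTRATES):
        raise ValueError("substrate pattern file is corrupt")
    return patterns


def match_sdp(sdp, pattern: SubstratePattern, max_novel: int = 1,
              query_id: str = "") -> SubstrateCall:
    """Score nine SDP residues against one substrate pattern.

    0 mismatches -> member; 1..max_novel -> member_novel, with the novel
    (position, residue) pairs recorded; more -> non_member.  The ``-``
    sentinel (unresolved feature) scores as a mismatch and is listed in
    ``unresolved_positions``.
    """
    sdp = tuple(sdp)
    if len(sdp) != 9:
        raise ValueError(f"SDP tuple must have 9 residues, got {len(sdp)}")
    mismatches = []
    unresolved = []
    for i, (res, allowed) in enumerate(zip(sdp, pattern.allowed), start=1):
        if res == UNRESOLVED:
            unresolved.append(i)
            mismatches.append(i)
        elif res not in allowed:
            mismatches.append(i)
    if not mismatches:
        status = MEMBER
    elif len(mismatches) <= max_novel:
        status = MEMBER_NOVEL
    else:
        status = NON_MEMBER
    novel = tuple((i, sdp[i - 1]) for i in mismatches
                  if status == MEMBER_NOVEL and i not in unresolved)
    return SubstrateCall(query_id=query_id, substrate=pattern.substrate,
                         status=status, mismatch_positions=tuple(mismatches),
                         novel_residues=novel,
                         unresolved_positions=tuple(unresolved))


def substrate_report(profiles: list[FeatureProfile], max_novel: int = 1
                     ) -> pd.DataFrame:
    """Six substrate calls per protein, as a tidy table.

    Columns: query_id, substrate, status, mismatch_positions,
    novel_residues.  Grouping by substrate and filtering on
    member/member_novel reproduces the published per-substrate blocks.
    """
    patterns = builtin_patterns()
    rows = []
    for prof in profiles:
        for pattern in patterns:
            call = match_sdp(prof.sdp, pattern, max_novel, query_id=prof.query_id)
            rows.append({
                "query_id": call.query_id,
                "substrate": call.substrate,
                "status": call.status,
                "mismatch_positions": ",".join(map(str, call.mismatch_positions)),
                "novel_residues": ",".join(f"SDP{i}={r}" for i, r in call.novel_residues),
            })
    return pd.DataFrame(rows, columns=["query_id", "substrate", "status",
                                       "mismatch_positions", "novel_residues"])
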