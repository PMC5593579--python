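"""Candidate selection and a canonical seed-site scanner.

Significant miRNAs down-regulated in the ALK+ group are promoted to
validation candidates when they satisfy at least one of three criteria:
(i) a predicted binding site in the ALK 3′-UTR, (ii) expression fold change
> 2, (iii) supporting literature.  The in-silico flag is an input boolean; it
can optionally be derived from the bundled seed scanner, which looks for
exact Watson–Crick matches of the miRNA seed (nucleotides 2–8) in a DNA UTR:

* 6mer — reverse complement of miRNA positions 2–7;
* 7mer — reverse complement of positions 2–8 (7mer-m8);
* 8mer — the 7mer-m8 match followed by an A opposite miRNA position 1.

Overlapping matches are reported once at the strongest type.  The scanner is
a deliberately minimal site finder (no thermodynamics, no conservation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .diffexp import DOWN_IN_ALK_POS, DiffExpTable
from .errors import ValidationError

_RNA = set("ACGU")
_DNA = set("ACGTN")
# RNA base -> complementary DNA base, read 3'->5' against the UTR
_RC = {"A": "T", "C": "G", "G": "C", "U": "A"}


@dataclass(frozen=True)
class SeedSite:
    """One seed match in a UTR; ``start`` is 0-based, half-open span."""

    start: int
    length: int
    site_type: str  # 6mer | 7mer | 8mer
    sequence: str

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end(self) -> int:
        return self.start + self.length


def _site_string(mirna: str, lo: int, hi: int) -> str:
    """UTR-strand (5'->3') DNA string pairing miRNA positions [lo, hi] (1-based)."""
    seed = mirna[lo - 1 : hi]
    return "".join(_RC[b] for b in reversed(seed))


def _find_all(hay: str, needle: str) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def scan_seed_sites(mirna_seq: str, utr_seq: str) -> list[SeedSite]:
    """All canonical 6/7/8mer seed matches of ``mirna_seq`` in ``utr_seq``.

    ``mirna_seq`` is RNA 5'→3' (≥ 8 nt), ``utr_seq`` DNA 5'→3'; ``N`` never
    matches.  Sites are returned in UTR order; a weaker site overlapping a
    stronger one is suppressed.
    """
    mirna = mirna_seq.upper()
    utr = utr_seq.upper()
    if len(mirna) < 8:
        raise ValidationError("miRNA must be at least 8 nt")
    if set(mirna) - _RNA:
        raise ValidationError(f"invalid miRNA alphabet: {sorted(set(mirna) - _RNA)}")
    if set(utr) - _DNA:
        raise ValidationError(f"invalid UTR alphabet: {sorted(set(utr) - _DNA)}")

    site7 = _site_string(mirna, 2, 8)
    site8 = site7 + "A"
    site6 = _site_string(mirna, 2, 7)

    sites: list[SeedSite] = []
    taken: list[tuple[int, int]] = []

    def overlaps(start: int, length: int) -> bool:
        return any(start < e and s < start + length for s, e in taken)

    for needle, kind in ((site8, "8mer"), (site7, "7mer"), (site6, "6mer")):
        for start in _find_all(utr, needle):
            if not overlaps(start, len(needle)):
                sites.append(SeedSite(start, len(needle), kind, needle))
                taken.append((start, start + len(needle)))
    return sorted(sites, key=lambda s: (s.start, -s.length))


@dataclass(frozen=True)
class CandidateAnnotation:
    """Per-miRNA inputs to the three-criterion filter."""

    probe_name: str
    predicted_alk_utr_target: bool = False
    literature_support: bool = False


def select_candidates(
    table: DiffExpTable,
    annotations: Sequence[CandidateAnnotation] | Mapping[str, CandidateAnnotation],
    fold_change_threshold: float = 2.0,
) -> pd.DataFrame:
    """Apply the three-criterion filter to significant down-in-ALK+ miRNAs.

    A record is a candidate iff predicted-target OR fold change >
    ``fold_change_threshold`` OR literature support.  Every significant
    down-regulated probe must have an annotation.  Returns the candidates in
    table order with per-criterion booleans.
    """
    if not isinstance(annotations, Mapping):
        annotations = {a.probe_name: a for a in annotations}
    sig = table.significant_records()
    down = sig[sig["direction"] == DOWN_IN_ALK_POS]
    rows = []
    for rec in down.itertuples(index=False):
        ann = annotations.get(rec.probe_name)
        if ann is None:
            raise ValidationError(
                f"missing annotation for significant probe '{rec.probe_name}'"
            )
        crit_target = bool(ann.predicted_alk_utr_target)
        crit_fc = rec.fold_change > fold_change_threshold
        crit_lit = bool(ann.literature_support)
        if crit_target or crit_fc or crit_lit:
            rows.append(
                {
                    "probe_name": rec.probe_name,
                    "fold_change": rec.fold_change,
                    "p_raw": rec.p_raw,
                    "predicted_alk_utr_target": crit_target,
                    "fold_change_gt_threshold": bool(crit_fc),
                    "literature_support": crit_lit,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "probe_name",
            "fold_change",
            "p_raw",
            "predicted_alk_utr_target",
            "fold_change_gt_threshold",
            "literature_support",
        ],
    )
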