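"""sgRNA demultiplexing: whitelist correction, UMI collapsing, singlet calling.

Pooled CRISPRi screens read out each cell's guide identity from a separate
sgRNA-enrichment library.  Observed 20-nt protospacer sequences are corrected
against the screen's whitelist allowing at most one mismatch, UMIs are
collapsed per (cell, guide), and each cell is called a singlet when one guide
clearly dominates its UMI counts: the top guide must hold at least 60% of the
cell's guide UMIs and be at least three-fold the runner-up.  Cells with 10 or
fewer total guide UMIs are too shallow to call and are dropped.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

_BASES = "ACGT"

#: sentinel stored in the variant index when two whitelist entries collide at
#: Hamming distance 1 from the same sequence
_AMBIGUOUS = "__ambiguous__"


@dataclass
class SgRNALibrary:
    """Whitelist of protospacers with target-gene and control annotations.

    ``entries`` columns: ``sgrna_id``, ``protospacer`` (20-nt uppercase ACGT),
    ``target_gene``, ``is_ntc`` (bool).  Non-targeting controls (NTCs) carry
    ``is_ntc=True`` and a shared ``target_gene`` label of ``"NTC"``.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"sgrna_id", "protospacer", "target_gene", "is_ntc"}
        missing = req - set(self.entries.columns)
        if missing:
            raise ValueError(f"whitelist missing columns: {sorted(missing)}")
        spacers = self.entries["protospacer"]
        if spacers.duplicated().any():
            raise ValueError("protospacers must be unique")
        bad = ~spacers.str.fullmatch("[ACGT]{20}")
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} protospacers are not 20-nt ACGT strings"
            )
        if self.entries["sgrna_id"].duplicated().any():
            raise ValueError("sgrna_id values must be unique")

    @property
    def sgrna_ids(self) -> list[str]:
        return self.entries["sgrna_id"].tolist()

    @property
    def ntc_ids(self) -> list[str]:
        return self.entries.loc[self.entries["is_ntc"], "sgrna_id"].tolist()

    def target_of(self, sgrna_id: str) -> str:
        row = self.entries.loc[self.entries["sgrna_id"] == sgrna_id]
        if row.empty:
            raise KeyError(sgrna_id)
        return str(row["target_gene"].iloc[0])

    @property
    def target_map(self) -> dict[str, str]:
        return dict(
            zip(self.entries["sgrna_id"], self.entries["target_gene"])
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SgRNALibrary":
        df = pd.read_csv(path, sep="\t")
        df["is_ntc"] = df["is_ntc"].astype(bool)
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)


class SgRNAMatcher:
    """One-mismatch corrector against a whitelist.

    Precomputes every sequence at Hamming distance <= 1 from each protospacer.
    A sequence reachable from two distinct entries is marked ambiguous and
    always rejected; `N` bases count as mismatches.
    """

    def __init__(self, library: SgRNALibrary):
        self.library = library
        self._exact: dict[str, str] = dict(
            zip(library.entries["protospacer"], library.entries["sgrna_id"])
        )
        self._index: dict[str, str] = {}
        for sgrna_id, spacer in zip(
            library.entries["sgrna_id"], library.entries["protospacer"]
        ):
            for i, ref_base in enumerate(spacer):
                for alt in _BASES:
                    if alt != ref_base:
                        self._add(spacer[:i] + alt + spacer[i + 1 :], sgrna_id)
                # N at any single position is one mismatch and correctable
                self._add(spacer[:i] + "N" + spacer[i + 1 :], sgrna_id)

    def _add(self, seq: str, sgrna_id: str) -> None:
        prev = self._index.get(seq)
        if prev is None:
            self._index[seq] = sgrna_id
        elif prev != sgrna_id:
            self._index[seq] = _AMBIGUOUS

    def correct(self, observed: str) -> Optional[str]:
        """Return the sgrna_id at Hamming distance <= 1, or None.

        An exact whitelist hit always wins; otherwise the unique entry at
        distance 1 is returned, and a distance-1 tie is rejected.
        """
        if len(observed) != 20:
            return None
        observed = observed.upper()
        exact = self._exact.get(observed)
        if exact is not None:
            return exact
        hit = self._index.get(observed)
        return None if hit in (None, _AMBIGUOUS) else hit


def correct_sgrna_sequence(
    observed: str, library: SgRNALibrary | SgRNAMatcher
) -> Optional[str]:
    """Correct one observed protospacer against the whitelist (<=1 mismatch).

    Returns the matching ``sgrna_id`` or ``None`` when the sequence is more
    than one mismatch from every entry or ties two entries at distance 1.
    """
    matcher = (
        library if isinstance(library, SgRNAMatcher) else SgRNAMatcher(library)
    )
    return matcher.correct(observed)


def dedup_sgrna_umis(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse identical UMIs per (cell, sgRNA) into molecule counts.

    ``records`` needs columns ``cell_barcode``, ``sgrna_id``, ``umi``.
    Returns a tidy table (cell_barcode, sgrna_id, umi_count); idempotent in
    the sense that re-collapsing the expanded output changes nothing.
    """
    if records.empty:
        return pd.DataFrame(columns=["cell_barcode", "sgrna_id", "umi_count"])
    counts = (
        records.drop_duplicates(["cell_barcode", "sgrna_id", "umi"])
        .groupby(["cell_barcode", "sgrna_id"], sort=True)
        .size()
        .reset_index(name="umi_count")
    )
    return counts


@dataclass
class SgRNACellCall:
    """Per-cell guide assignment outcome."""

    cell_barcode: str
    counts: dict[str, int] = field(default_factory=dict)
    total_umis: int = 0
    status: str = "no_sgrna"  # singlet | doublet | no_sgrna | low_umi
    assigned_sgrna: Optional[str] = None


def call_singlet(
    counts: dict[str, int],
    cell_barcode: str = "",
    min_total_umis: int = 10,
    top_fraction: float = 0.60,
    fold_over_second: float = 3.0,
) -> SgRNACellCall:
    """Call one cell's guide status from deduplicated UMI counts.

    Rules (all on UMI counts, boundaries inclusive on the cell's side):

    * total UMIs must be strictly greater than ``min_total_umis``, else
      ``low_umi``;
    * singlet iff the top guide holds >= ``top_fraction`` of the total AND
      is >= ``fold_over_second`` times the second guide (a second count of 0
      passes the fold rule); a tie for the top guide is a doublet;
    * anything else is a doublet; empty counts give ``no_sgrna``.
    """
    call = SgRNACellCall(cell_barcode=cell_barcode, counts=dict(counts))
    positive = {k: v for k, v in counts.items() if v > 0}
    call.total_umis = int(sum(positive.values()))
    if not positive:
        call.status = "no_sgrna"
        return call
    if call.total_umis <= min_total_umis:
        call.status = "low_umi"
        return call
    ranked = sorted(positive.items(), key=lambda kv: (-kv[1], kv[0]))
    top_id, top = ranked[0]
    second = ranked[1][1] if len(ranked) > 1 else 0
    tie_for_top = len(ranked) > 1 and ranked[1][1] == top
    frac_ok = top >= top_fraction * call.total_umis
    fold_ok = second == 0 or top >= fold_over_second * second
    if frac_ok and fold_ok and not tie_for_top:
        call.status = "singlet"
        call.assigned_sgrna = top_id
    else:
        call.status = "doublet"
    return call


def call_singlets(
    counts: pd.DataFrame,
    min_total_umis: int = 10,
    top_fraction: float = 0.60,
    fold_over_second: float = 3.0,
) -> pd.DataFrame:
    """Call singlet status for every cell in a (cell, sgRNA, umi_count) table.

    Returns one row per cell: cell_barcode, status, assigned_sgrna,
    total_umis, top_umis, second_umis.
    """
    rows = []
    for cell, grp in counts.groupby("cell_barcode", sort=True):
        cdict = dict(zip(grp["sgrna_id"], grp["umi_count"].astype(int)))
        call = call_singlet(
            cdict,
            cell_barcode=str(cell),
            min_total_umis=min_total_umis,
            top_fraction=top_fraction,
            fold_over_second=fold_over_second,
        )
        ranked = sorted(call.counts.values(), reverse=True)
        rows.append(
            {
                "cell_barcode": call.cell_barcode,
                "status": call.status,
                "assigned_sgrna": call.assigned_sgrna,
                "total_umis": call.total_umis,
                "top_umis": ranked[0] if ranked else 0,
                "second_umis": ranked[1] if len(ranked) > 1 else 0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_barcode",
            "status",
            "assigned_sgrna",
            "total_umis",
            "top_umis",
            "second_umis",
        ],
    )


@dataclass
class SgRNAReadLayout:
    """Fixed-offset layout of the guide-enrichment reads.

    All offsets are 0-based on the single (merged) read carrying the cell
    barcode, UMI, a constant anchor and the 20-nt protospacer.  One mismatch
    is tolerated when matching the anchor.
    """

    cell_barcode_slice: tuple[int, int] = (0, 10)
    umi_slice: tuple[int, int] = (10, 20)
    anchor: str = "GTTTAAGAGC"
    anchor_offset: int = 20
    protospacer_offset: int = 30

    def anchor_matches(self, seq: str) -> bool:
        window = seq[self.anchor_offset : self.anchor_offset + len(self.anchor)]
        if len(window) != len(self.anchor):
            return False
        mism = sum(a != b for a, b in zip(window, self.anchor))
        return mism <= 1


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            yield header.strip()[1:], seq


def parse_sgrna_fastq(
    fastq: str | Path,
    library: SgRNALibrary,
    layout: SgRNAReadLayout | None = None,
) -> pd.DataFrame:
    """Extract and correct guide records from an enrichment-library FASTQ.

    Reads failing the anchor match (>1 mismatch) or whose protospacer cannot
    be corrected are discarded.  Returns UMI-level records (cell_barcode,
    sgrna_id, umi) ready for :func:`dedup_sgrna_umis`.
    """
    layout = layout or SgRNAReadLayout()
    matcher = SgRNAMatcher(library)
    cells, ids, umis = [], [], []
    for _name, seq in _iter_fastq(fastq):
        if not layout.anchor_matches(seq):
            continue
        spacer = seq[
            layout.protospacer_offset : layout.protospacer_offset + 20
        ]
        sgrna_id = matcher.correct(spacer)
        if sgrna_id is None:
            continue
        cells.append(seq[slice(*layout.cell_barcode_slice)])
        umis.append(seq[slice(*layout.umi_slice)])
        ids.append(sgrna_id)
    return pd.DataFrame(
        {"cell_barcode": cells, "sgrna_id": ids, "umi": umis}
    )
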