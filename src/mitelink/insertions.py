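"""PopoolationTE2-style signature tables -> frequency matrix -> zygosity.

Reference insertions are evidenced by paired forward/reverse (F/R)
read-pair signatures whose frequencies are averaged; non-reference
insertions carry a single joint FR signature.  Per-sample frequencies are
classified as homozygous occupied (> 0.7), heterozygous (0.3-0.7, both
boundaries included) or homozygous empty (< 0.3); absence of any
signature is frequency 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

ZYGOSITY_ORDER = ("hom_empty", "het", "hom_occupied")
#: integer encoding used in the serialised zygosity matrix
ZYGOSITY_CODE = {"hom_empty": 0, "het": 1, "hom_occupied": 2}
VALID_SIGNATURES = {"F", "R", "FR"}
VALID_MODES = {"reference", "nonreference"}
EXTERNAL_CALLS = ("hom_empty", "het", "hom_occupied", "no_amplification")


class SignatureParseError(ValueError):
    pass


@dataclass
class InsertionSite:
    """One insertion locus keyed by (chrom, pos, family, mode)."""

    chrom: str
    pos: int
    family: str
    mode: str
    freq: dict[str, float] = field(default_factory=dict)
    superfamily: str = "uc"

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.family}:{self.mode}"

    def frequency(self, sample: str) -> float:
        return self.freq.get(sample, 0.0)


def classify_zygosity(freq: float, low: float = 0.3, high: float = 0.7) -> str:
    """Total, piecewise-constant map from frequency to zygosity call.

    Frequencies above ``high`` are homozygous occupied, below ``low``
    homozygous empty; the closed band [low, high] is heterozygous.
    """
    if not (0.0 <= freq <= 1.0):
        raise ValueError(f"frequency {freq} outside [0, 1]")
    if freq > high:
        return "hom_occupied"
    if freq >= low:
        return "het"
    return "hom_empty"


def read_signatures(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str,
                                            "family": str})
    required = ["sample", "chrom", "pos", "family", "signature",
                "frequency", "mode"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SignatureParseError(f"signature table missing columns {missing}")
    return df


def parse_signatures(
    table: pd.DataFrame, catalogue: pd.DataFrame | None = None
) -> list[InsertionSite]:
    """Collapse signature rows into per-site frequency maps.

    Reference-mode rows are paired by (sample, chrom, pos, family) and the
    F and R frequencies averaged; an unpaired F or R row is used as-is with
    a warning.  Non-reference rows use the FR frequency directly.
    Reference and non-reference sites at coincident loci stay distinct.
    """
    sup = {}
    if catalogue is not None:
        sup = dict(zip(catalogue["family"], catalogue["superfamily"]))
    sites: dict[tuple, InsertionSite] = {}
    n_unpaired = 0
    for line_no, row in enumerate(table.itertuples(index=False), start=2):
        freq = float(row.frequency)
        if not (0.0 <= freq <= 1.0):
            raise SignatureParseError(
                f"line {line_no}: frequency {row.frequency} outside [0, 1]"
            )
        if row.signature not in VALID_SIGNATURES:
            raise SignatureParseError(
                f"line {line_no}: unknown signature code {row.signature!r}"
            )
        if row.mode not in VALID_MODES:
            raise SignatureParseError(
                f"line {line_no}: unknown mode {row.mode!r}"
            )
    for (chrom, pos, family, mode), grp in table.groupby(
        ["chrom", "pos", "family", "mode"], sort=True
    ):
        site = InsertionSite(
            chrom=str(chrom), pos=int(pos), family=str(family), mode=str(mode),
            superfamily=sup.get(str(family), "uc"),
        )
        for sample, sgrp in grp.groupby("sample"):
            sigs = dict(zip(sgrp["signature"], sgrp["frequency"]))
            if mode == "reference":
                if "F" in sigs and "R" in sigs:
                    freq = (float(sigs["F"]) + float(sigs["R"])) / 2.0
                else:
                    freq = float(next(iter(sigs.values())))
                    n_unpaired += 1
            else:
                freq = float(sigs.get("FR", next(iter(sigs.values()))))
            site.freq[str(sample)] = freq
        sites[(str(chrom), int(pos), str(family), str(mode))] = site
    if n_unpaired:
        logger.warning("%d unpaired reference F/R signatures", n_unpaired)
    return [sites[k] for k in sorted(sites)]


def frequency_matrix(
    sites: list[InsertionSite], samples: list[str]
) -> pd.DataFrame:
    mat = pd.DataFrame(
        {s: [site.frequency(s) for site in sites] for s in samples},
        index=[site.key for site in sites],
    )
    mat.index.name = "site"
    return mat


def zygosity_matrix(
    sites: list[InsertionSite], samples: list[str],
    low: float = 0.3, high: float = 0.7,
) -> pd.DataFrame:
    """Complete sample x site matrix of zygosity labels."""
    mat = pd.DataFrame(
        {s: [classify_zygosity(site.frequency(s), low, high) for site in sites]
         for s in samples},
        index=[site.key for site in sites],
    )
    mat.index.name = "site"
    return mat


def zygosity_counts(
    sites: list[InsertionSite], samples: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Per-family and per-superfamily hom/het counts, plus per-sample
    copy numbers (calls other than hom_empty)."""
    zyg = zygosity_matrix(sites, samples)
    fam = pd.Series([s.family for s in sites], index=zyg.index)
    sup = pd.Series([s.superfamily for s in sites], index=zyg.index)
    def counts_by(group: pd.Series) -> pd.DataFrame:
        rows = {}
        for name in sorted(group.unique()):
            sub = zyg.loc[group == name]
            rows[name] = {
                "hom_occupied": int((sub == "hom_occupied").to_numpy().sum()),
                "het": int((sub == "het").to_numpy().sum()),
            }
        out = pd.DataFrame.from_dict(rows, orient="index")
        out.index.name = "group"
        return out
    copies = (zyg != "hom_empty").sum(axis=0)
    copies.name = "copies"
    return counts_by(fam), counts_by(sup), copies


def _pct(count: int, total: int) -> float:
    """Percentage rounded half-up to 2 decimals (printed-table convention)."""
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


@dataclass
class ConcordanceTable:
    """In-silico vs external (e.g. PCR) call confusion summary."""

    counts: dict[tuple[str, str], int]
    no_amplification: int
    total: int

    @property
    def correct(self) -> int:
        return sum(
            n for (a, b), n in self.counts.items() if a == b
        )

    @property
    def incorrect(self) -> int:
        return sum(
            n for (a, b), n in self.counts.items() if a != b
        )

    @property
    def percent_correct(self) -> float:
        return _pct(self.correct, self.total)

    @property
    def percent_incorrect(self) -> float:
        return _pct(self.incorrect, self.total)

    def percent(self, in_silico: str, external: str) -> float:
        return _pct(self.counts.get((in_silico, external), 0), self.total)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), n in sorted(self.counts.items()):
            rows.append({"in_silico": a, "external": b, "count": n,
                         "percent": _pct(n, self.total)})
        rows.append({"in_silico": "any", "external": "no_amplification",
                     "count": self.no_amplification,
                     "percent": _pct(self.no_amplification, self.total)})
        rows.append({"in_silico": "total_correct", "external": "",
                     "count": self.correct, "percent": self.percent_correct})
        rows.append({"in_silico": "total_incorrect", "external": "",
                     "count": self.incorrect, "percent": self.percent_incorrect})
        rows.append({"in_silico": "total", "external": "", "count": self.total,
                     "percent": 100.0})
        return pd.DataFrame(rows)


def summarize_concordance(
    pairs: list[tuple[str, str]]
) -> ConcordanceTable:
    """Tally (in-silico call, external call) pairs into a confusion summary.

    External ``no_amplification`` results are tallied separately and count
    toward neither correct nor incorrect; correct calls are the three
    concordant diagonal cells.
    """
    if not pairs:
        raise ValueError("empty pair list")
    counts: dict[tuple[str, str], int] = {}
    no_amp = 0
    for in_silico, external in pairs:
        if in_silico not in ZYGOSITY_ORDER:
            raise ValueError(f"unknown in-silico call {in_silico!r}")
        if external not in EXTERNAL_CALLS:
            raise ValueError(f"unknown external call {external!r}")
        if external == "no_amplification":
            no_amp += 1
        else:
            counts[(in_silico, external)] = counts.get((in_silico, external), 0) + 1
    return ConcordanceTable(counts=counts, no_amplification=no_amp,
                            total=len(pairs))
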