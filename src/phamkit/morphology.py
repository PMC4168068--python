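"""Electron-micrograph measurement summaries, morphotype grouping, and
TMP-based identification of co-isolated phages.

Virion features are summarized as mean +/- sample (n-1) standard
deviation, one decimal, as in the published measurement tables.
Morphotypes: a contractile sheath makes a myovirus; otherwise the capsid
aspect ratio (height/width) separates elongated-capsid siphoviruses
(ratio above the cutoff, default 1.2) from round-capsid ones; phages with
no usable measurements stay unclassified.

Co-isolated phages are matched to their genomes by rank order: tape
measure protein (TMP) gene length correlates positively with tail length,
so the longest TMP gene belongs to the phage with the longest tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from typing import Mapping, Sequence

from ._util import mean_sd, round_half_up

FEATURES = (
    "capsid_height",
    "capsid_width",
    "tail_length",
    "tail_width",
    "sheath_length",
    "sheath_width",
)

MYOVIRUS = "myovirus"
SIPHO_ELONGATED = "siphovirus_elongated"
SIPHO_ROUND = "siphovirus_round"
SIPHO_UNCLASSIFIED = "siphovirus_unclassified"

DEFAULT_ELONGATION_CUTOFF = 1.2


@dataclass(frozen=True)
class MeasurementSet:
    phage: str
    feature: str
    replicates: tuple[float, ...]

    def __post_init__(self):
        if self.feature not in FEATURES:
            raise ValueError(f"unknown feature {self.feature!r}")
        if any(v <= 0 for v in self.replicates):
            raise ValueError("measurements must be positive (nm)")
        object.__setattr__(self, "replicates", tuple(self.replicates))


@dataclass(frozen=True)
class MorphotypeCall:
    phage: str
    morphotype: str


@dataclass(frozen=True)
class TmpTailMatch:
    assignments: dict[str, str]  # genome -> imaged phage
    tmp_ratios: tuple[float, ...]  # between consecutive ranked genomes
    tail_ratios: tuple[float, ...]

    @property
    def tmp_ratio(self) -> float:
        return self.tmp_ratios[0]

    @property
    def tail_ratio(self) -> float:
        return self.tail_ratios[0]


def summarize(ms: MeasurementSet) -> tuple[float, float]:
    """Mean and sample sd of the replicates, one decimal, half-up."""
    if len(ms.replicates) < 2:
        raise ValueError(
            f"{ms.phage}/{ms.feature}: sample sd undefined for "
            f"{len(ms.replicates)} replicate(s)"
        )
    return mean_sd(ms.replicates, ndigits=1)


def classify_morphotype(
    phage: str,
    contractile_sheath: bool,
    capsid_height: float | None,
    capsid_width: float | None,
    elongation_cutoff: float = DEFAULT_ELONGATION_CUTOFF,
) -> MorphotypeCall:
    if contractile_sheath:
        return MorphotypeCall(phage, MYOVIRUS)
    if capsid_height is None or capsid_width is None:
        return MorphotypeCall(phage, SIPHO_UNCLASSIFIED)
    ratio = capsid_height / capsid_width
    if ratio > elongation_cutoff:
        return MorphotypeCall(phage, SIPHO_ELONGATED)
    return MorphotypeCall(phage, SIPHO_ROUND)


def match_coisolated(
    tmp_lengths: Mapping[str, float],
    tail_lengths: Mapping[str, float],
) -> TmpTailMatch:
    """Rank-order bijection between genomes (by TMP gene length, bp) and
    imaged phages (by tail length, nm).

    Ratios between consecutive ranked pairs are reported to two decimals.
    Tied lengths make the assignment ambiguous and raise.
    """
    if len(tmp_lengths) != len(tail_lengths):
        raise ValueError("need equally many genomes and imaged phages")
    if not tmp_lengths:
        raise ValueError("nothing to match")
    if len(set(tmp_lengths.values())) != len(tmp_lengths):
        raise ValueError("tied TMP gene lengths: assignment ambiguous")
    if len(set(tail_lengths.values())) != len(tail_lengths):
        raise ValueError("tied tail lengths: assignment ambiguous")
    genomes = sorted(tmp_lengths, key=lambda g: -tmp_lengths[g])
    images = sorted(tail_lengths, key=lambda p: -tail_lengths[p])
    assignments = dict(zip(genomes, images))

    def ratios(ordered, value_of):
        out = []
        for hi, lo in zip(ordered, ordered[1:]):
            r = Decimal(repr(float(value_of[hi]))) / Decimal(repr(float(value_of[lo])))
            out.append(round_half_up(r, 2))
        return tuple(out)

    return TmpTailMatch(
        assignments=assignments,
        tmp_ratios=ratios(genomes, tmp_lengths),
        tail_ratios=ratios(images, tail_lengths),
    )


def summary_table(
    measurements: Sequence[MeasurementSet],
) -> "pandas.DataFrame":
    """Per-phage 'mean +/- sd' cells, one row per phage, one column per
    feature."""
    import pandas as pd

    cells: dict[str, dict[str, str]] = {}
    for ms in measurements:
        mean, sd = summarize(ms)
        cells.setdefault(ms.phage, {})[ms.feature] = f"{mean} ± {sd}"
    frame = pd.DataFrame.from_dict(cells, orient="index")
    return frame.reindex(columns=[f for f in FEATURES if f in frame.columns])


def read_measurements_tsv(path) -> list[MeasurementSet]:
    """Read a (phage, feature, value_nm) TSV into MeasurementSets."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    expected = {"phage", "feature", "value_nm"}
    if not expected.issubset(df.columns):
        raise ValueError(f"measurements TSV needs columns {sorted(expected)}")
    out = []
    for (phage, feature), grp in df.groupby(["phage", "feature"], sort=True):
        out.append(
            MeasurementSet(
                phage=str(phage),
                feature=str(feature),
                replicates=tuple(float(v) for v in grp["value_nm"]),
            )
        )
    return out
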