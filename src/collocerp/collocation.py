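"""Mutual-information scoring and condition assignment for adjective-noun bigrams.

Collocations are operationalized by pointwise mutual information (MI)
computed from corpus frequencies::

    MI = log2( (AB * N) / (A * B * K) )

where ``A`` and ``B`` are the occurrence counts of the two words, ``AB`` the
count of their co-occurrence within a span of ``K`` word positions, and ``N``
the corpus size.  When all counts are expressed as per-million relative
frequencies, ``N`` cancels and the formula reduces to::

    MI = log2( f_AB * 1e6 / (f_A * f_B * K) )

with ``1e6`` the per-million scale.  Items are assigned to the collocation
condition when MI exceeds an upper bound, to the non-collocation condition
when MI falls below a lower bound, and are excluded when they land in the
buffer zone between the bounds.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Scale factor turning per-million relative frequencies back into a
#: dimensionless probability ratio (the corpus size cancels at this scale).
PER_MILLION = 1.0e6

#: Default condition bounds in bits: non-collocations at or below the lower
#: bound, collocations at or above the upper bound; the open interval between
#: them is the buffer zone.
DEFAULT_LOW = 4.83
DEFAULT_HIGH = 6.72


class ConditionLabel(str, enum.Enum):
    """Experimental condition assigned to a scored bigram."""

    COLLOCATION = "collocation"
    NON_COLLOCATION = "non_collocation"
    BUFFER_EXCLUDED = "buffer_excluded"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class BigramRecord:
    """One adjective-noun bigram with per-million corpus frequencies.

    ``node_word`` is the noun (the critical word), ``collocate`` the
    adjective; MI is symmetric in the two frequencies so the order only
    matters for bookkeeping.  ``span_K`` is the co-occurrence window width.
    """

    node_word: str
    collocate: str
    freq_node: float
    freq_collocate: float
    freq_bigram: float
    span_K: int = 1

    def __post_init__(self) -> None:
        freqs = (self.freq_node, self.freq_collocate, self.freq_bigram)
        if not all(np.isfinite(f) for f in freqs):
            raise ValueError("frequencies must be finite")
        if any(f < 0 for f in freqs):
            raise ValueError("frequencies must be non-negative")
        if self.span_K < 1:
            raise ValueError(f"span_K must be >= 1, got {self.span_K}")
        if self.freq_bigram > min(self.freq_node, self.freq_collocate) > 0:
            # corpus rounding can produce this; not an error
            warnings.warn(
                f"bigram frequency {self.freq_bigram} exceeds a component "
                f"frequency for '{self.collocate} {self.node_word}'",
                stacklevel=2,
            )

    @property
    def bigram(self) -> str:
        return f"{self.collocate} {self.node_word}"


@dataclass(frozen=True)
class AssociationScore:
    """MI in bits; the flag marks the AB=0 -> MI:=0 convention."""

    mi_bits: float
    zero_bigram_convention_applied: bool = False


def compute_mi(record: BigramRecord) -> AssociationScore:
    """Score one bigram.

    A zero bigram (or component) frequency would send the log to -inf /
    leave it undefined; by convention such items score 0 bits, mirroring
    how corpus tools print them.
    """
    if record.freq_bigram == 0 or record.freq_node == 0 or record.freq_collocate == 0:
        return AssociationScore(0.0, zero_bigram_convention_applied=True)
    ratio = (record.freq_bigram * PER_MILLION) / (
        record.freq_node * record.freq_collocate * record.span_K
    )
    return AssociationScore(float(np.log2(ratio)))


def score_table(records: list[BigramRecord]) -> list[AssociationScore]:
    """Element-wise :func:`compute_mi`, preserving input order."""
    if not records:
        raise ValueError("record list is empty")
    scores = []
    for i, rec in enumerate(records):
        try:
            scores.append(compute_mi(rec))
        except ValueError as err:
            raise ValueError(f"row {i} ({rec!r}): {err}") from err
    return scores


def classify_bigram(
    score: AssociationScore | float,
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
    decimals: int | None = 2,
) -> ConditionLabel:
    """Assign a condition from an MI score.

    The bounds are stated at two-decimal precision, so by default the score
    is rounded to the same precision before comparison; boundary items
    (MI equal to a bound) belong to the adjacent condition, not the buffer.
    Pass ``decimals=None`` to compare unrounded values.
    """
    if low > high:
        raise ValueError(f"low bound {low} exceeds high bound {high}")
    mi = score.mi_bits if isinstance(score, AssociationScore) else float(score)
    if decimals is not None:
        mi = round(mi, decimals)
    if mi <= low:
        return ConditionLabel.NON_COLLOCATION
    if mi >= high:
        return ConditionLabel.COLLOCATION
    return ConditionLabel.BUFFER_EXCLUDED


# ---------------------------------------------------------------------------
# bigram tables on disk
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["freq_collocate_pm", "freq_node_pm", "freq_bigram_pm"]


def read_bigram_table(path_or_buffer) -> pd.DataFrame:
    """Read a delimited bigram table.

    Required columns: ``node_word``, ``collocate``, ``freq_node_pm``,
    ``freq_collocate_pm``, ``freq_bigram_pm``; optional ``printed_mi`` and
    ``table_group``.
    """
    df = pd.read_csv(path_or_buffer, sep="\t")
    missing = {"node_word", "collocate", *_TABLE_COLUMNS} - set(df.columns)
    if missing:
        raise ValueError(f"bigram table missing columns: {sorted(missing)}")
    return df


def load_item_table() -> pd.DataFrame:
    """Load the packaged 26-item adjective-noun stimulus table."""
    ref = resources.files("collocerp.data").joinpath("table1.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        return read_bigram_table(fh)


def records_from_table(df: pd.DataFrame, span_K: int = 1) -> list[BigramRecord]:
    return [
        BigramRecord(
            node_word=row.node_word,
            collocate=row.collocate,
            freq_node=row.freq_node_pm,
            freq_collocate=row.freq_collocate_pm,
            freq_bigram=row.freq_bigram_pm,
            span_K=span_K,
        )
        for row in df.itertuples()
    ]


def score_and_classify(
    df: pd.DataFrame,
    span_K: int = 1,
    low: float = DEFAULT_LOW,
    high: float = DEFAULT_HIGH,
) -> pd.DataFrame:
    """Score every row of a bigram table and attach condition labels.

    Returns a copy of the table with ``mi_bits``, ``zero_convention`` and
    ``condition`` columns appended.
    """
    records = records_from_table(df, span_K=span_K)
    scores = score_table(records)
    out = df.copy()
    out["mi_bits"] = [s.mi_bits for s in scores]
    out["zero_convention"] = [s.zero_bigram_convention_applied for s in scores]
    out["condition"] = [str(classify_bigram(s, low=low, high=high)) for s in scores]
    return out


# ---------------------------------------------------------------------------
# condition matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PropertyMatch:
    """Rank-sum comparison of one item property between conditions."""

    property_name: str
    mean_a: float
    mean_b: float
    smd: float  # absolute standardized mean difference
    u_statistic: float
    p_value: float
    matched: bool


@dataclass(frozen=True)
class MatchingReport:
    """Per-property matching summary between the two conditions."""

    condition_a: str
    condition_b: str
    n_a: int
    n_b: int
    properties: dict[str, PropertyMatch]

    @property
    def all_matched(self) -> bool:
        return all(p.matched for p in self.properties.values())


def _abs_smd(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float(abs(a.mean() - b.mean()) / pooled)


def matching_report(
    df: pd.DataFrame,
    condition_col: str = "table_group",
    alpha_matched: float = 0.2,
) -> MatchingReport:
    """Check that the two conditions are matched on word length and frequency.

    For each item the word length is the total character count of the two
    words and the word frequency is the mean of the two per-million
    component frequencies.  Each property is compared between conditions
    with a two-sided Mann-Whitney rank-sum test; the conditions count as
    matched on a property when p > ``alpha_matched``.  The absolute
    standardized mean difference is reported alongside.
    """
    groups = df[condition_col].unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 conditions, got {list(groups)}")
    cond_a, cond_b = groups
    sub_a = df[df[condition_col] == cond_a]
    sub_b = df[df[condition_col] == cond_b]
    if sub_a.empty or sub_b.empty:
        raise ValueError("a condition has no items")

    def _props(sub: pd.DataFrame) -> dict[str, np.ndarray]:
        length = (
            sub["collocate"].str.len() + sub["node_word"].str.len()
        ).to_numpy(dtype=float)
        freq = ((sub["freq_collocate_pm"] + sub["freq_node_pm"]) / 2.0).to_numpy(
            dtype=float
        )
        return {"word_length": length, "word_frequency_pm": freq}

    props_a, props_b = _props(sub_a), _props(sub_b)
    results: dict[str, PropertyMatch] = {}
    for name in props_a:
        a, b = props_a[name], props_b[name]
        if np.array_equal(np.sort(a), np.sort(b)):
            u, p = float(len(a) * len(b) / 2.0), 1.0
        else:
            u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        results[name] = PropertyMatch(
            property_name=name,
            mean_a=float(a.mean()),
            mean_b=float(b.mean()),
            smd=_abs_smd(a, b),
            u_statistic=float(u),
            p_value=float(p),
            matched=bool(p > alpha_matched),
        )
    return MatchingReport(
        condition_a=str(cond_a),
        condition_b=str(cond_b),
        n_a=len(sub_a),
        n_b=len(sub_b),
        properties=results,
    )
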