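"""Crowdsourced vote aggregation into retained squirrel observations.

Images are classified by many participants for (a) the number of
squirrels present (zero / one / two_or_more) and (b) the coat color of
each squirrel (gray / melanic / other / unclear).  An image is retained
when the modal answer to the count question reaches the agreement
threshold (default 80%) with at least the minimum number of votes, the
count is nonzero, and the color of at least one squirrel in the image
reaches the same threshold.  "unclear" is a valid vote (it counts in
the denominator of the agreement share) but never becomes a retained
observation.  Images with two morphs present yield one observation per
resolved color slot.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

COUNT_LABELS = ("zero", "one", "two_or_more")
COLOR_LABELS = ("gray", "melanic", "other", "unclear")

__all__ = [
    "VoteRecord",
    "ConsensusReport",
    "consensus_label",
    "resolve_image",
    "resolve_votes",
    "filter_observations",
    "merge_sources",
    "records_from_long",
]


@dataclass
class VoteRecord:
    """All votes for one image."""

    image_id: str
    count_votes: list[str]
    color_votes: list[list[str]]  # one list per squirrel slot
    location: tuple[float, float] | None = None
    in_native_range: bool = True


@dataclass
class ConsensusReport:
    """Stage-by-stage image tallies through the retention path."""

    submitted: int = 0
    met_count_threshold: int = 0
    count_zero: int = 0
    count_one: int = 0
    count_two_plus: int = 0
    met_color_threshold: int = 0
    dropped_no_location: int = 0
    dropped_out_of_range: int = 0
    final: int = 0

    def check(self) -> None:
        assert self.met_count_threshold <= self.submitted
        assert (
            self.count_zero + self.count_one + self.count_two_plus
            == self.met_count_threshold
        )
        assert self.met_color_threshold <= self.count_one + self.count_two_plus
        assert (
            self.final
            == self.met_color_threshold
            - self.dropped_no_location
            - self.dropped_out_of_range
        )

    def to_dict(self) -> dict:
        return asdict(self)


def consensus_label(votes, threshold: float = 0.8, min_votes: int = 1):
    """Modal label if its share reaches ``threshold``; else ``None``.

    All votes (including "unclear") count in the denominator.  Ties at
    the mode cannot reach a threshold > 0.5 and resolve to ``None``.
    """
    votes = list(votes)
    if not votes:
        raise ValueError("empty vote list")
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    if min_votes < 1:
        raise ValueError("min_votes must be >= 1")
    if len(votes) < min_votes:
        return None
    labels, counts = np.unique(votes, return_counts=True)
    top = counts.max()
    if (counts == top).sum() > 1:
        # a tie can never reach a >0.5 share; defensive
        return None
    share = top / len(votes)
    # half-ulp slack so that e.g. 8/10 >= 0.8 holds exactly
    if share + 1e-12 < threshold:
        return None
    return str(labels[np.argmax(counts)])


def resolve_image(
    record: VoteRecord, threshold: float = 0.8, min_votes: int = 1
) -> tuple[list[str], dict]:
    """Resolve one image to its retained coat colors.

    Returns ``(colors, flags)`` where ``colors`` holds one entry per
    resolved, non-"unclear" squirrel slot (empty when the image is
    dropped) and ``flags`` records which stage the image reached.
    """
    flags = {
        "count_label": None,
        "failed_count": False,
        "zero_count": False,
        "failed_color": False,
    }
    count = consensus_label(record.count_votes, threshold, min_votes)
    flags["count_label"] = count
    if count is None:
        flags["failed_count"] = True
        return [], flags
    if count == "zero":
        flags["zero_count"] = True
        return [], flags
    colors = []
    for slot_votes in record.color_votes:
        lab = consensus_label(slot_votes, threshold, min_votes)
        if lab is not None and lab != "unclear":
            colors.append(lab)
    if not colors:
        flags["failed_color"] = True
    return colors, flags


def records_from_long(votes: pd.DataFrame, images: pd.DataFrame | None = None):
    """Build :class:`VoteRecord` objects from a long-format vote table.

    ``votes`` columns: image_id, question ("count"/"color"), slot,
    label, voter_id.  ``images`` (optional) columns: image_id, x, y,
    in_native_range.
    """
    meta = {}
    if images is not None:
        for row in images.itertuples(index=False):
            loc = None
            if not (pd.isna(row.x) or pd.isna(row.y)):
                loc = (float(row.x), float(row.y))
            meta[row.image_id] = (loc, bool(row.in_native_range))
    records = []
    for image_id, grp in votes.groupby("image_id", sort=True):
        count_votes = grp.loc[grp["question"] == "count", "label"].tolist()
        color = grp[grp["question"] == "color"]
        color_votes = [
            slot_grp.sort_values("voter_id")["label"].tolist()
            for _, slot_grp in color.groupby("slot", sort=True)
        ]
        loc, in_range = meta.get(image_id, (None, True))
        records.append(
            VoteRecord(
                image_id=str(image_id),
                count_votes=count_votes,
                color_votes=color_votes,
                location=loc,
                in_native_range=in_range,
            )
        )
    return records


def resolve_votes(
    votes: pd.DataFrame,
    images: pd.DataFrame | None = None,
    threshold: float = 0.8,
    min_votes: int = 1,
) -> tuple[pd.DataFrame, ConsensusReport]:
    """Aggregate a long-format vote table into retained observations.

    Returns the observation table (obs_id, image_id, x, y, color,
    source, plus location/range flags) and a :class:`ConsensusReport`
    with image-level stage counts.  Location and native-range filtering
    is applied by :func:`filter_observations`.
    """
    records = records_from_long(votes, images)
    report = ConsensusReport(submitted=len(records))
    rows = []
    for rec in records:
        colors, flags = resolve_image(rec, threshold, min_votes)
        if flags["failed_count"]:
            continue
        report.met_count_threshold += 1
        if flags["zero_count"]:
            report.count_zero += 1
            continue
        if flags["count_label"] == "one":
            report.count_one += 1
        else:
            report.count_two_plus += 1
        if not colors:
            continue
        report.met_color_threshold += 1
        has_loc = rec.location is not None
        if not has_loc:
            report.dropped_no_location += 1
        elif not rec.in_native_range:
            report.dropped_out_of_range += 1
        else:
            report.final += 1
        for slot, color in enumerate(colors):
            rows.append(
                {
                    "image_id": rec.image_id,
                    "slot": slot,
                    "x": rec.location[0] if has_loc else np.nan,
                    "y": rec.location[1] if has_loc else np.nan,
                    "color": color,
                    "has_location": has_loc,
                    "in_native_range": rec.in_native_range,
                    "source": "votes",
                }
            )
    obs = pd.DataFrame(
        rows,
        columns=[
            "image_id",
            "slot",
            "x",
            "y",
            "color",
            "has_location",
            "in_native_range",
            "source",
        ],
    )
    obs.insert(0, "obs_id", [f"vote_{k:06d}" for k in range(len(obs))])
    report.check()
    return obs, report


def filter_observations(obs: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop records missing a location, then records outside the native
    range; tally each stage."""
    if "has_location" in obs.columns:
        has_loc = obs["has_location"].astype(bool).to_numpy()
    else:
        has_loc = (~(obs["x"].isna() | obs["y"].isna())).to_numpy()
    in_range = (
        obs["in_native_range"].astype(bool).to_numpy()
        if "in_native_range" in obs.columns
        else np.ones(len(obs), dtype=bool)
    )
    kept = obs[has_loc & in_range].reset_index(drop=True)
    tally = {
        "input": int(len(obs)),
        "dropped_no_location": int((~has_loc).sum()),
        "dropped_out_of_range": int((has_loc & ~in_range).sum()),
        "final": int(len(kept)),
    }
    assert (
        tally["final"]
        == tally["input"] - tally["dropped_no_location"] - tally["dropped_out_of_range"]
    )
    return kept, tally


def merge_sources(vote_obs: pd.DataFrame, direct_obs: pd.DataFrame) -> pd.DataFrame:
    """Concatenate vote-derived and directly reported observations.

    Both tables must share the observation schema; obs_ids must be
    globally unique across sources.
    """
    if len(direct_obs) == 0:
        return vote_obs.copy()
    direct = direct_obs.copy()
    if "source" not in direct.columns:
        direct["source"] = "direct_report"
    merged = pd.concat([vote_obs, direct], ignore_index=True, sort=False)
    dup = merged["obs_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate obs_id across sources: {sorted(merged.loc[dup, 'obs_id'].unique())[:5]}"
        )
    return merged
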