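#!/usr/bin/env python
"""Aggregate the crowd votes into retained observations.

Applies the 80% agreement threshold (>= 10 votes) to the simulated
vote records and reports the image count surviving each stage.
"""

import json

from _common import get_study, outdir, scratchdir
from urbancline.consensus import filter_observations, resolve_votes


def main() -> None:
    study = get_study()
    out = outdir()
    obs, report = resolve_votes(study.votes, study.images, threshold=0.8, min_votes=10)
    kept, tally = filter_observations(obs)

    (out / "consensus_report.json").write_text(
        json.dumps({"stages": report.to_dict(), "filtering": tally}, indent=2)
    )
    kept.to_csv(scratchdir() / "consensus_observations.csv", index=False)

    r = report
    print(f"{r.submitted} images submitted; {r.met_count_threshold} met the count threshold")
    print(f"  zero: {r.count_zero}, one: {r.count_one}, two_or_more: {r.count_two_plus}")
    print(f"{r.met_color_threshold} resolved a coat color; {r.final} survived location/range filters")
    print(f"{tally['final']} observation records written ({len(kept) - r.final} extra from two-morph images)")


if __name__ == "__main__":
    main()
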