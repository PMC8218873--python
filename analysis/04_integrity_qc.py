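#!/usr/bin/env python
"""Integrity statistics of the wireless run + a 24-hour-style timeline.

Reports packet-drop percentage and Severely Errored Seconds for the chain
run of step 02, then builds a synthetic day-long disruption timeline (300 s
segments, annotated gaps) to exercise the cause-table accounting.
"""

import json
from pathlib import Path

from bcilink import formats
from bcilink.qc import disruption_timeline, packet_drop_stats

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    log = formats.read_receiver_log(OUT / "receiver_log.json")
    report = packet_drop_stats(log)
    (OUT / "integrity_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    print(f"drop rate {report.drop_pct:.3f}% over {report.total_seconds:.0f} s; "
          f"{report.ses_count} severely errored seconds")

    # synthetic 24 h: gaps from caregiver blockage, battery swaps, storage faults
    gaps = [(14_400.0, 20_400.0), (30_000.0, 31_500.0), (52_000.0, 52_900.0),
            (70_000.0, 70_300.0), (80_000.0, 81_500.0)]
    notes = [(14_400.0, 20_400.0, "caregiver activity"),
             (30_000.0, 31_500.0, "battery change"),
             (52_000.0, 52_900.0, "file storage fault")]
    tl = disruption_timeline(24 * 3600.0, gaps=gaps, annotations=notes)
    (OUT / "disruption_timeline.json").write_text(json.dumps({
        "n_segments": tl.n_segments,
        "n_disrupted": tl.n_disrupted,
        "disrupted_minutes": tl.disrupted_minutes,
        "causes_minutes": tl.cause_table.to_dict(),
    }, indent=2))
    print(f"24 h timeline: {tl.n_segments} segments, {tl.n_disrupted} disrupted "
          f"({tl.disrupted_minutes:.0f} min); causes: {tl.cause_table.to_dict()}")


if __name__ == "__main__":
    main()
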