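"""Score the three behavioral assays from raw event inputs.

Novel object recognition, Y-maze spontaneous alternation, and elevated
plus maze, each on the conventional 0-100 percent scale.
"""

import transcord as tc

# NOR: 30 s on the novel object, 10 s on the familiar one
ri = tc.recognition_index(tc.ExplorationTimes(tn=30, tf=10))
print(f"recognition index: {ri:.1f}%  (50% = no preference, higher = intact memory)")

# Y-maze: each entry event in order; ABCAB CAB... alternates perfectly
seq = tc.ArmEntrySequence(list("ABCABCAB"))
alt = tc.count_alternations(seq)
pct = tc.spontaneous_alternation_pct(seq)
print(f"Y-maze: {len(seq)} entries, {alt} alternations -> {pct:.1f}% "
      "(chance level is ~50% for a random walker)")

# EPM: 3 open-arm entries of 12 total, 60 s of 300 s in the open arms
epm = tc.EpmCounts(open_entries=3, closed_entries=9, open_time=60, total_time=300)
print(f"EPM open-arm entries: {tc.open_arm_entry_pct(epm):.1f}%, "
      f"open-arm time: {tc.open_arm_time_pct(epm):.1f}% "
      "(lower values indicate more anxiety-like avoidance)")
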