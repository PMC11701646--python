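"""Evidence-channel score combination and network-mode consistency.

Builds a three-protein network by hand, combines channel subscores under a
prior, recomputes the combined score with the text-mining channel disabled,
and checks a physical sub-network against its functional parent.
"""

from assocnet import (
    Edge,
    Network,
    check_mode_consistency,
    combine_channel_scores,
    filter_by_confidence,
    recompute_combined,
)

# Two independent channels at 0.5 jointly support the pair more strongly
# than either alone: noisy-OR gives 1 - 0.5*0.5 = 0.75.
both = combine_channel_scores({"experiments": 0.5, "textmining": 0.5})
print(f"experiments 0.5 + textmining 0.5, prior 0   -> combined {both:.4f}")

# With a prior of 0.1 the evidence is first deflated, then the prior restored.
with_prior = combine_channel_scores({"experiments": 0.5, "textmining": 0.5}, prior=0.1)
print(f"experiments 0.5 + textmining 0.5, prior 0.1 -> combined {with_prior:.5f}")

net = Network(
    ["A", "B", "C"],
    [
        Edge("A", "B", {"experiments": 0.5, "textmining": 0.5}, both),
        Edge("B", "C", {"textmining": 0.7}, 0.7),
    ],
)

# Disabling text mining removes the only evidence for B--C: the edge drops.
no_tm = recompute_combined(net, enabled=["experiments"])
print(f"channels without textmining: {len(no_tm.edges)} edge(s) remain, "
      f"A--B combined {no_tm.edges[0].combined:.2f}")

strong = filter_by_confidence(net, cutoff=0.75)
print(f"confidence cutoff 0.75 keeps {len(strong.edges)} of {len(net.edges)} edges")

# A physical subset must stay within the functional parent at <= scores.
physical = Network(["A", "B"], [Edge("A", "B", {"experiments": 0.5}, 0.5)],
                   mode="physical")
violations = check_mode_consistency(physical, net)
print(f"mode-consistency violations: {len(violations)} (0 means the physical "
      "network is contained in the functional one)")
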