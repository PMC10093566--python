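"""Score one lymph node with the ratio features and both composite scores.

Takes a node's SUVmax plus the patient's four reference uptakes (primary
tumor, liver, brainstem, contralateral lung), computes the ratio features,
and applies the quantified visual score (1-3) and the five-condition
multifactorial score (0-5), both dichotomized at >= 3.
"""

from petln import ReferenceUptake, classify, compute_ratios, multifactorial_score, visual_score_q

node_suvmax = 7.8
refs = ReferenceUptake(primary_suvmax=9.5, liver_suvmax=3.0,
                       brainstem_suvmax=6.8, lung_suvmax=0.6)

ratios = compute_ratios(node_suvmax, refs)
print(f"node SUVmax        {node_suvmax:.2f}")
print(f"node/primary       {ratios.ln_to_primary:.3f}")
print(f"node/liver         {ratios.ln_to_liver:.3f}")
print(f"node/brainstem     {ratios.ln_to_brainstem:.3f}")
print(f"node/lung          {ratios.ln_to_lung:.3f}")

visual = visual_score_q(node_suvmax, refs.liver_suvmax, refs.primary_suvmax)
multi = multifactorial_score(node_suvmax, ratios)
print(f"visual score       {visual.score}  -> {classify(visual.score, cutoff=3, max_score=3)}")
print(f"multifactorial     {multi.score} (flags {multi.flags_string}) "
      f"-> {classify(multi.score, cutoff=3)}")

# Flags I-V report SUVmax >= 5.495 and the four ratios against their
# published cut-offs (0.457 / 1.374 / 0.749 / 4.593); one point each, and
# a total of >= 3 classifies the node as malignant.
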