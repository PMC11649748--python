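"""Predictor-score categorization and the 2-of-3 damaging consensus.

SIFT calls a variant deleterious (D) below 0.05; PolyPhen-2 calls it
possibly damaging (P) from 0.446 and probably damaging (PD) from 0.908;
REVEL calls it damaging (D) from 0.5. A variant is retained when at least
two of the three available scores are damaging; records with no scores
(splice-region/intronic) bypass the consensus rather than failing it.
"""

from pedsieve import ScoreBundle, categorize, consensus_pass

profiles = {
    "candidate missense (PolyPhen-only)": ScoreBundle(sift=0.171, polyphen=0.997, revel=0.478),
    "two-tool damaging missense": ScoreBundle(sift=0.008, polyphen=0.979, revel=0.364),
    "benign missense": ScoreBundle(sift=0.6, polyphen=0.1, revel=0.2),
    "splice region (no scores)": ScoreBundle(),
}

for label, scores in profiles.items():
    cats = categorize(scores)
    n_damaging, n_evaluable, passes = consensus_pass(scores)
    print(
        f"{label:36s} SIFT={cats.sift:2s} PolyPhen={cats.polyphen:2s} "
        f"REVEL={cats.revel:2s}  damaging {n_damaging}/{n_evaluable} "
        f"-> {'pass' if passes else 'fail'}"
    )
# Note the first profile: damaging by PolyPhen alone, so it FAILS the strict
# 2-of-3 rule even though it is the kind of variant the pipeline exists to
# find — run the funnel with apply_consensus=False or min_damaging=1 to keep
# such records, and the report will show the override.
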