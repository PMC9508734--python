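"""Reference feature vectors of the seven ambiguous neuroblastoma cases.

These encode the published evidence panels of the study cohort's seven
samples that could not be classified by the strict APB/CCA/telomerase
rule: NB05 and NB45 resolve to TEL+, NB43, NB46, NB50, NB54 and NB68 to
ALT+. Continuous values are representative encodings of the published
qualitative statements (high/low telomere content, TERRA at/above or
below the ALT-group mean, singleton depletion), not measured numbers;
the resolution rule consumes them only through its thresholds.
"""
from __future__ import annotations

from .classify import ClassifierConfig, SampleFeatures

#: Classifier configuration used with the reference cases. The singleton
#: depletion reference (the ALT-group mean log2 singleton ratio) has no
#: published value and is set to -1.0 for the encoded panels.
REFERENCE_CONFIG = ClassifierConfig(singleton_alt_mean=-1.0)

AMBIGUOUS_CASES: dict[str, SampleFeatures] = {
    # CCA-positive, APB-negative; MNA, high TERT expression and high
    # telomerase activity; low TC/TERRA, no depletion, no insertions.
    "NB05": SampleFeatures(
        sample_id="NB05",
        mna=True,
        tert_ra=False,
        tert_expr_high=True,
        telomerase_activity_high=True,
        apb=False,
        cca=True,
        atrx_mut=False,
        tc_ratio=0.8,
        terra_total=0.001,
        ttt_ggg_singleton_log2=0.0,
        n_insertions=0,
    ),
    # APB-positive, CCA-negative; TERT rearrangement and high TERT
    # expression despite high TC and insertions; no TERRA expression.
    "NB45": SampleFeatures(
        sample_id="NB45",
        mna=False,
        tert_ra=True,
        tert_expr_high=True,
        apb=True,
        cca=False,
        atrx_mut=False,
        tc_ratio=3.5,
        terra_total=0.0005,
        ttt_ggg_singleton_log2=0.0,
        n_insertions=2,
    ),
    # APB-positive, CCA-negative; TERRA expression, high TC, insertions
    # and low TERT expression.
    "NB43": SampleFeatures(
        sample_id="NB43",
        mna=False,
        tert_ra=False,
        tert_expr_high=False,
        apb=True,
        cca=False,
        atrx_mut=False,
        tc_ratio=4.0,
        terra_total=0.012,
        ttt_ggg_singleton_log2=0.0,
        n_insertions=2,
    ),
    # Only APB available (CCA missing); ATRX mutation, high TC,
    # singleton depletion and insertions.
    "NB46": SampleFeatures(
        sample_id="NB46",
        mna=False,
        tert_ra=False,
        tert_expr_high=False,
        apb=True,
        cca=None,
        atrx_mut=True,
        tc_ratio=5.0,
        ttt_ggg_singleton_log2=-2.0,
        n_insertions=1,
    ),
    # APB- and CCA-positive despite high TERT expression; ATRX mutation,
    # high TC, TERRA, insertions, singleton depletion.
    "NB50": SampleFeatures(
        sample_id="NB50",
        mna=False,
        tert_ra=False,
        tert_expr_high=True,
        apb=True,
        cca=True,
        atrx_mut=True,
        tc_ratio=6.0,
        terra_total=0.015,
        ttt_ggg_singleton_log2=-2.2,
        n_insertions=2,
    ),
    # APB- and CCA-positive despite high TERT expression; high TC, long
    # TRF, low singleton fraction, one insertion.
    "NB54": SampleFeatures(
        sample_id="NB54",
        mna=False,
        tert_ra=False,
        tert_expr_high=True,
        apb=True,
        cca=True,
        atrx_mut=False,
        tc_ratio=5.5,
        trf_kb=11.0,
        ttt_ggg_singleton_log2=-1.8,
        n_insertions=1,
    ),
    # APB-positive, CCA-negative; particularly high TC, insertions, low
    # fraction of TVR singletons, no TERT activation.
    "NB68": SampleFeatures(
        sample_id="NB68",
        mna=False,
        tert_ra=False,
        tert_expr_high=False,
        apb=True,
        cca=False,
        atrx_mut=False,
        tc_ratio=9.0,
        terra_total=0.003,
        ttt_ggg_singleton_log2=-2.5,
        n_insertions=3,
    ),
}

EXPECTED_RESOLUTIONS = {
    "NB05": "TEL_pos",
    "NB45": "TEL_pos",
    "NB43": "ALT_pos",
    "NB46": "ALT_pos",
    "NB50": "ALT_pos",
    "NB54": "ALT_pos",
    "NB68": "ALT_pos",
}
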