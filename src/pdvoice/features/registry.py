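"""The 132-entry dysphonia feature registry.

Feature names and order are fixed and versioned: every extraction run
emits exactly these names in exactly this order.  Global index layout
(1-based) mirrors the standard battery this package follows at family
level:

* 1-30    jitter variants (vocal-fold period perturbation)
* 31-51   shimmer variants (cycle amplitude perturbation)
* 52-58   HNR/NHR and Glottal Quotient variants
* 59-82   energy-type measures: RPDE, DFA, PPE, GNE, VFER, EMD-ER
* 83-124  MFCC summaries (14 coefficients x static/delta/delta-delta)
* 125-132 F0 summary statistics and normative deviations
"""

from __future__ import annotations

REGISTRY_VERSION = "1.0"

JITTER_FEATURES = [
    # on cycle periods T
    "jitter_T_mad_rel", "jitter_T_mad_abs", "jitter_T_rap", "jitter_T_ppq5",
    "jitter_T_ppq11", "jitter_T_ddp", "jitter_T_std_rel", "jitter_T_p5p95_rel",
    "jitter_T_rmsd_rel", "jitter_T_log_mad",
    # on the per-cycle F0 contour
    "jitter_F0_mad_rel", "jitter_F0_mad_abs", "jitter_F0_rap", "jitter_F0_ppq5",
    "jitter_F0_ppq11", "jitter_F0_ddp", "jitter_F0_std_rel", "jitter_F0_p5p95_rel",
    "jitter_F0_rmsd_rel", "jitter_F0_log_mad",
    # on the semitone pitch contour
    "jitter_st_mad", "jitter_st_std", "jitter_st_rmsd", "jitter_st_p5p95", "jitter_st_ppq5",
    # robust / trimmed variants on T
    "jitter_T_trim_mad_rel", "jitter_T_trim_std_rel", "jitter_T_maxd_rel",
    "jitter_T_med_mad_rel", "jitter_T_med_dev_rel",
]

SHIMMER_FEATURES = [
    "shimmer_A_mad_rel", "shimmer_A_db", "shimmer_A_apq3", "shimmer_A_apq5",
    "shimmer_A_apq11", "shimmer_A_dda", "shimmer_A_std_rel", "shimmer_A_p5p95_rel",
    "shimmer_A_rmsd_rel", "shimmer_A_med_mad_rel", "shimmer_A_log_mad",
    "shimmer_E_mad_rel", "shimmer_E_std_rel", "shimmer_E_apq5", "shimmer_E_apq11",
    "shimmer_A_trim_mad_rel", "shimmer_A_trim_std_rel", "shimmer_A_maxd_rel",
    "shimmer_db_std", "shimmer_db_p5p95", "shimmer_db_rmsd",
]

HNR_GQ_FEATURES = [
    "hnr_mean_db", "hnr_std_db", "nhr_mean", "nhr_std",
    "gq_prc5_95", "gq_std_open_rel", "gq_std_closed_rel",
]

NONLINEAR_FEATURES = ["rpde", "dfa", "ppe"]

GNE_FEATURES = [
    "gne_mean", "gne_std", "gne_snr_tkeo", "gne_snr_seo", "gne_nsr_tkeo", "gne_nsr_seo",
]

VFER_FEATURES = [
    "vfer_mean", "vfer_std", "vfer_entropy",
    "vfer_snr_tkeo", "vfer_snr_seo", "vfer_snr_entropy",
    "vfer_nsr_tkeo", "vfer_nsr_seo", "vfer_nsr_entropy",
]

EMD_FEATURES = [
    "imf_snr_seo", "imf_snr_tkeo", "imf_snr_entropy",
    "imf_nsr_seo", "imf_nsr_tkeo", "imf_nsr_entropy",
]

_MFCC_BASE = ["log_energy"] + [f"mfcc_{i}" for i in range(13)]
MFCC_FEATURES = (
    [f"{n}_mean" for n in _MFCC_BASE]
    + [f"{n}_delta" for n in _MFCC_BASE]
    + [f"{n}_delta2" for n in _MFCC_BASE]
)

F0_FEATURES = [
    "f0_mean", "f0_median", "f0_std", "f0_min", "f0_max", "f0_range",
    "f0_norm_dev_abs", "f0_norm_dev_rel",
]

FAMILIES: dict[str, list[str]] = {
    "jitter": JITTER_FEATURES,
    "shimmer": SHIMMER_FEATURES,
    "hnr_gq": HNR_GQ_FEATURES,
    "nonlinear": NONLINEAR_FEATURES,
    "gne": GNE_FEATURES,
    "vfer": VFER_FEATURES,
    "emd": EMD_FEATURES,
    "mfcc": MFCC_FEATURES,
    "f0": F0_FEATURES,
}

REGISTRY: list[str] = [name for fam in FAMILIES.values() for name in fam]
FAMILY_OF: dict[str, str] = {name: fam for fam, names in FAMILIES.items() for name in names}

N_FEATURES = len(REGISTRY)
assert N_FEATURES == 132, f"registry must contain 132 features, got {N_FEATURES}"
assert len(JITTER_FEATURES) == 30 and len(SHIMMER_FEATURES) == 21
assert len(MFCC_FEATURES) == 42 and len(F0_FEATURES) == 8


def family_slice(family: str) -> list[str]:
    return list(FAMILIES[family])


def global_index(name: str) -> int:
    """1-based global index of a feature in the registry."""
    return REGISTRY.index(name) + 1
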