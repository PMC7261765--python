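# Canonical white-matter region sets for FA event-based modelling.
#
# Labels are ASCII tokens; `tract` gives the anatomical name. The
# corticospinal tract is subdivided along the MNI z-axis into three
# segments whose boundaries follow the posterior limb of the internal
# capsule; `mni_z` records the closed interval of each segment in MNI mm
# (.inf / -.inf denote unbounded ends). The corpus callosum is subdivided
# into genu / body / splenium and is never split by hemisphere; in the
# split set every other tract appears once per hemisphere (suffix _L/_R).
combined:
  - {label: CST_inf, tract: Corticospinal tract (inferior), hemisphere: both, mni_z: [-.inf, -5]}
  - {label: CST_mid, tract: Corticospinal tract (middle), hemisphere: both, mni_z: [-4, 18]}
  - {label: CST_sup, tract: Corticospinal tract (superior), hemisphere: both, mni_z: [19, .inf]}
  - {label: CC_genu, tract: Corpus callosum (genu), hemisphere: both}
  - {label: CC_body, tract: Corpus callosum (body), hemisphere: both}
  - {label: CC_splenium, tract: Corpus callosum (splenium), hemisphere: both}
  - {label: Cingulum, tract: Cingulum (dorsal section), hemisphere: both}
  - {label: SLF, tract: Superior longitudinal fasciculus, hemisphere: both}
  - {label: ILF, tract: Inferior longitudinal fasciculus, hemisphere: both}
  - {label: IFOF, tract: Inferior fronto-occipital fasciculus, hemisphere: both}
  - {label: UF, tract: Uncinate fasciculus, hemisphere: both}
split:
  - {label: CST_inf_L, tract: Corticospinal tract (inferior), hemisphere: L, mni_z: [-.inf, -5]}
  - {label: CST_inf_R, tract: Corticospinal tract (inferior), hemisphere: R, mni_z: [-.inf, -5]}
  - {label: CST_mid_L, tract: Corticospinal tract (middle), hemisphere: L, mni_z: [-4, 18]}
  - {label: CST_mid_R, tract: Corticospinal tract (middle), hemisphere: R, mni_z: [-4, 18]}
  - {label: CST_sup_L, tract: Corticospinal tract (superior), hemisphere: L, mni_z: [19, .inf]}
  - {label: CST_sup_R, tract: Corticospinal tract (superior), hemisphere: R, mni_z: [19, .inf]}
  - {label: CC_genu, tract: Corpus callosum (genu), hemisphere: both}
  - {label: CC_body, tract: Corpus callosum (body), hemisphere: both}
  - {label: CC_splenium, tract: Corpus callosum (splenium), hemisphere: both}
  - {label: Cingulum_L, tract: Cingulum (dorsal section), hemisphere: L}
  - {label: Cingulum_R, tract: Cingulum (dorsal section), hemisphere: R}
  - {label: SLF_L, tract: Superior longitudinal fasciculus, hemisphere: L}
  - {label: SLF_R, tract: Superior longitudinal fasciculus, hemisphere: R}
  - {label: ILF_L, tract: Inferior longitudinal fasciculus, hemisphere: L}
  - {label: ILF_R, tract: Inferior longitudinal fasciculus, hemisphere: R}
  - {label: IFOF_L, tract: Inferior fronto-occipital fasciculus, hemisphere: L}
  - {label: IFOF_R, tract: Inferior fronto-occipital fasciculus, hemisphere: R}
  - {label: UF_L, tract: Uncinate fasciculus, hemisphere: L}
  - {label: UF_R, tract: Uncinate fasciculus, hemisphere: R}
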