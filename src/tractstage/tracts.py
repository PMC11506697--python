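"""JHU white-matter tract labels and the focus-relative (lateralized) ROI space.

The biomarker set is the 20-tract JHU tractography atlas summary used by
TBSS-style pipelines: 9 left/right tract pairs plus the two midline forceps.
Patients with a unilateral epileptic focus are analysed in a focus-relative
space where each paired tract is relabelled ipsilateral/contralateral; the
forceps are midline structures and keep their names.
"""

from __future__ import annotations

#: Paired (lateralized) tracts, one entry per left/right pair.
PAIRED_TRACTS: tuple[str, ...] = (
    "ATR",      # anterior thalamic radiation
    "CST",      # corticospinal tract
    "Cing_C",   # cingulum (cingulate gyrus)
    "Cing_H",   # cingulum (hippocampus)
    "IFOF",     # inferior fronto-occipital fasciculus
    "ILF",      # inferior longitudinal fasciculus
    "SLF",      # superior longitudinal fasciculus
    "SLF_T",    # superior longitudinal fasciculus, temporal projection
    "UF",       # uncinate fasciculus
)

#: Midline tracts, not lateralized.
MIDLINE_TRACTS: tuple[str, ...] = ("Forceps_major", "Forceps_minor")

#: Column order of the raw FA table: L/R for each pair, then the forceps.
TRACT_LABELS: tuple[str, ...] = tuple(
    f"{t}_{side}" for t in PAIRED_TRACTS for side in ("L", "R")
) + MIDLINE_TRACTS

#: Column order of the lateralized abnormality matrix: ipsi/contra for each
#: pair, then the forceps. This order is fixed and part of the file format.
ROI_LABELS: tuple[str, ...] = tuple(
    f"{t}_{side}" for t in PAIRED_TRACTS for side in ("ipsi", "contra")
) + MIDLINE_TRACTS

N_TRACTS = len(TRACT_LABELS)
assert N_TRACTS == len(ROI_LABELS) == 20


def validate_tract_labels(labels) -> None:
    """Check that `labels` is exactly the 18 paired + 2 midline tract set."""
    got = set(labels)
    want = set(TRACT_LABELS)
    if got != want:
        missing = sorted(want - got)
        extra = sorted(got - want)
        raise ValueError(
            f"tract labels do not match the 20-tract JHU set; "
            f"missing={missing}, unexpected={extra}"
        )
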