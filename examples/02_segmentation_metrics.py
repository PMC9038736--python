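"""Evaluate simulated observer segmentations against the reference masks with
the three agreement metrics (DSC, CSA error, ASD) and summarize as
median [Q1, Q3] per fracture class — the layout used for reporting
segmentation accuracy on patient cohorts.
"""

from vertomics import evaluate_case, make_cohort, summarize_by_group
from vertomics.experiments import COHORT_PARAMS

cases = make_cohort(4, 4, COHORT_PARAMS, seed=11, n_observers=1,
                    observer_displacement_mm=1.0)
results = [
    evaluate_case(c.observer_masks[0], c.truth_mask,
                  case_id=f"{c.patient_id}:{c.vertebra_id}", label=c.label)
    for c in cases
]
table = summarize_by_group(results)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(
    "\nDSC near 1 and ASD well under the 1 mm displacement budget show the"
    "\nsimulated observers stay close to the reference masks."
)
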