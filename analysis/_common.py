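"""Shared configuration for the numbered analysis scripts.

One phantom cohort at the emulated study's sample sizes (31 controls, 33
patients) with the fornix-like signature: the two minor tensor eigenvalues
raised by 0.2e-3 mm^2/s in the middle fifth of the tract (RD up, FA down,
AD unchanged there) and PANSS total negatively coupled to each patient's
true FA at the effect locus.
"""

from pathlib import Path

from limbictract.pipeline import PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_config() -> PipelineConfig:
    return PipelineConfig(
        output_dir=str(RESULTS / "study"),
        seed=42,
        n_control=31,
        n_patient=33,
        effect_segment=(0.4, 0.6),
        effect_delta=0.2e-3,
        panss_coupling={"panss_total": -0.6},
        noise_sigma=0.03,
    )
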