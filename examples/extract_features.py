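"""Extract the 48-feature vector from one synthetic 4-channel recording.

Builds a 4-min recording with moderate burst suppression and an F3-P4 phase
coupling, preprocesses it (2-min epochs, zero-phase 0.1-40 Hz Butterworth,
>200 μV rejection) and prints the headline features.
"""
import numpy as np

from fpcoma import (PatientProfile, gen_coupled_recording,
                    preprocess_recording, epoch_features,
                    aggregate_patient_features)

profile = PatientProfile(
    supp_frac=0.3,                    # ~30% of time in suppression
    amp_scale=25.0,                   # burst amplitude, μV
    band_mix=(0.9, 0.05, 0.03, 0.02),  # δ-dominant background
    coupling={("F3", "P4"): (0.7, np.pi / 2, 0.5)},
    seed=7,
)
rec = gen_coupled_recording(profile, duration_s=240.0, subject_id="demo")

retained, qc_log = preprocess_recording(rec)
print(f"{len(retained)}/{len(qc_log)} epochs retained after QC")

pf = aggregate_patient_features([epoch_features(e) for e in retained],
                                subject_id=rec.subject_id)
for name in ("bsr", "rms", "beta_alpha", "pli_F3_P4", "plv_F3_P4", "f_h"):
    print(f"  {name:12s} = {pf.features[name]:.3f}")

print("\nBSR tracks the configured suppressed fraction; RMS ≈ amp_scale/√2; "
      "PLI(F3,P4) is high\nbecause the pair shares a strongly coupled source "
      "at a π/2 lag.")
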