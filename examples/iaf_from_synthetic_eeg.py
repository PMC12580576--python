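"""Estimate individual alpha frequency three ways from synthetic EEG.

Synthesizes five 60-s eyes-closed trials (19 parieto-occipital channels)
for an observer with a known alpha peak, then estimates the smoothed
peak alpha frequency (PAF), the alpha-band centre of gravity (COG) and
the aperiodic-corrected peak (F_PAF).
"""

from mpiaf import CohortSpec, RecordingSpec, estimate_iaf, make_cohort, synthesize_eeg

observer = make_cohort(CohortSpec(n_observers=1, seed=7))[0]
print(f"true alpha centre frequency: {observer.alpha_cf:.3f} Hz")

recording = synthesize_eeg(observer, RecordingSpec(), seed=7)
est = estimate_iaf(recording)
print(f"PAF   = {est.paf:.3f} Hz  ({est.n_channels_paf}/19 channels)")
print(f"COG   = {est.cog:.3f} Hz  ({est.n_channels_cog}/19 channels)")
print(f"F_PAF = {est.f_paf:.3f} Hz  ({est.n_trials_fpaf}/5 trials accepted)")

# PAF and F_PAF track the true peak closely; COG sits slightly lower
# because the fixed 7-13 Hz window weights the 1/f background, which the
# aperiodic-corrected F_PAF removes.
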