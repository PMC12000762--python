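"""Generate a synthetic territorial call and save it as a WAV file.

Samples one individual's acoustic profile from the population model,
renders a four-note "ge-ga-ga-ge" syllable at 20 dB SNR, and prints the
ground-truth note boundaries alongside the profile parameters.
"""

from callcensus.pipeline_io import write_audio
from callcensus.synth import render_call, sample_population

(profile,) = sample_population(1, seed=42)
audio, note_intervals = render_call(profile, snr_db=20.0, seed=0)
write_audio("synthetic_call.wav", audio)

print(f"individual {profile.individual_id}")
print(f"  fundamentals (Hz): {profile.fundamentals.round(0)}")
print(f"  note durations (s): {profile.note_durations.round(3)}")
print(f"  total syllable: {profile.total_duration:.3f} s")
print("  true note intervals in the rendered buffer:")
for j, (t0, t1) in enumerate(note_intervals, start=1):
    print(f"    note {j}: {t0:.3f} - {t1:.3f} s")
print("wrote synthetic_call.wav (22,050 Hz mono, 16-bit)")
# The four notes carry this bird's individual signature: its pitch, note
# timing, emphasis pattern and contour are stable across its calls.
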