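import numpy as np

from tacitload import RawRecording


def tone_recording(freq, rate=512.0, duration=4.0, amp=1.0, n_channels=2,
                   channels=None, events=()):
    """A pure-sinusoid recording on every channel, for filter-response tests."""
    t = np.arange(int(duration * rate)) / rate
    x = amp * np.sin(2 * np.pi * freq * t)
    channels = channels or [f"ch{i}" for i in range(n_channels)]
    return RawRecording(
        channels=channels, rate=rate,
        signal=np.tile(x, (len(channels), 1)), events=list(events),
    )


def central_rms(rec, margin=0.25):
    """RMS of the central portion of every channel (avoids filter edges)."""
    n = rec.n_samples
    lo, hi = int(margin * n), int((1 - margin) * n)
    return np.sqrt(np.mean(rec.signal[:, lo:hi] ** 2, axis=1))
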