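"""Timing and geometry constants of the 4-channel A-mode acquisition system.

The device polls its four single-element transducers round-robin at an
80 Hz tick clock: each 12.5 ms tick refreshes exactly one channel, so a
full update of all four channels takes 50 ms.  Channels 1 and 3 face the
anterior (quadriceps) muscle group and channels 2 and 4 the posterior
(hamstrings) group, so each muscle group is sampled at 40 Hz.  Every
reading is a 1-D echo-amplitude profile of 997 samples spanning 3.94 cm
of soft tissue.
"""

SAMPLE_RATE_HZ = 80.0
N_CHANNELS = 4
FRAME_SAMPLES = 997
PENETRATION_DEPTH_CM = 3.94
DEPTH_PER_SAMPLE_CM = PENETRATION_DEPTH_CM / FRAME_SAMPLES

TICK_INTERVAL_MS = 1000.0 / SAMPLE_RATE_HZ               # 12.5 ms
FULL_REFRESH_MS = TICK_INTERVAL_MS * N_CHANNELS          # 50 ms
CHANNEL_REFRESH_HZ = SAMPLE_RATE_HZ / N_CHANNELS         # 20 Hz per channel

# anterior pair targets the quadriceps, posterior pair the hamstrings
MUSCLE_GROUP_OF_CHANNEL = {1: "quadriceps", 2: "hamstrings",
                           3: "quadriceps", 4: "hamstrings"}
CHANNELS_PER_MUSCLE_GROUP = 2
MUSCLE_GROUP_RATE_HZ = CHANNEL_REFRESH_HZ * CHANNELS_PER_MUSCLE_GROUP  # 40 Hz


def channel_at_tick(tick: int) -> int:
    """Channel refreshed at an 80 Hz tick (round-robin 1,2,3,4,1,...)."""
    return (int(tick) % N_CHANNELS) + 1
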