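# Default twenty-behavior catalogue.
#
# Per behavior: Izhikevich hyperparameters (a, b, c, d), initial membrane
# potential v0 (u0 defaults to b*v0 when omitted), default sample count
# n_steps (duration = n_steps * dt, default dt = 0.25 ms), and the injected
# current protocol.  Protocol times are [fraction, offset_ms] pairs resolved
# as fraction*duration + offset_ms, so stimulus onsets scale with the
# duration while pulse widths and dynamically critical gaps stay absolute.
# Amplitudes are constants or [start, end] linear ramps.
a:
  label: tonic spiking
  params: {a: 0.02, b: 0.2, c: -65.0, d: 6.0}
  v0: -70.0
  n_steps: 20000
  segments:
    - {start: [0.1, 0.0], end: [1.0, 0.0], amp: 14.0}
b:
  label: phasic spiking
  params: {a: 0.02, b: 0.25, c: -65.0, d: 6.0}
  v0: -64.0
  n_steps: 9000
  segments:
    - {start: [0.2, 0.0], end: [1.0, 0.0], amp: 0.5}
c:
  label: tonic bursting
  params: {a: 0.02, b: 0.2, c: -50.0, d: 2.0}
  v0: -70.0
  n_steps: 19000
  segments:
    - {start: [0.1, 0.0], end: [1.0, 0.0], amp: 15.0}
d:
  label: phasic bursting
  params: {a: 0.02, b: 0.25, c: -55.0, d: 0.05}
  v0: -64.0
  n_steps: 20000
  segments:
    - {start: [0.2, 0.0], end: [1.0, 0.0], amp: 0.6}
e:
  label: mixed mode
  params: {a: 0.02, b: 0.2, c: -55.0, d: 4.0}
  v0: -70.0
  n_steps: 20000
  segments:
    - {start: [0.1, 0.0], end: [1.0, 0.0], amp: 10.0}
f:
  label: spike frequency adaptation
  params: {a: 0.01, b: 0.2, c: -65.0, d: 8.0}
  v0: -70.0
  n_steps: 20000
  segments:
    - {start: [0.1, 0.0], end: [1.0, 0.0], amp: 30.0}
g:
  label: class 1 excitable
  params: {a: 0.02, b: -0.1, c: -55.0, d: 6.0}
  v0: -60.0
  n_steps: 20000
  segments:
    - {start: [0.1, 0.0], end: [1.0, 0.0], amp: [0.0, 30.0]}
h:
  label: class 2 excitable
  params: {a: 0.2, b: 0.26, c: -65.0, d: 0.0}
  v0: -64.0
  n_steps: 20000
  baseline: -0.5
  segments:
    - {start: [0.1, 0.0], end: [1.0, 0.0], amp: [-0.5, 3.55]}
i:
  label: spike latency
  params: {a: 0.02, b: 0.2, c: -65.0, d: 6.0}
  v0: -70.0
  n_steps: 20000
  segments:
    - {start: [0.2, 0.0], end: [0.2, 3.0], amp: 7.4}
j:
  label: subthreshold oscillations
  params: {a: 0.05, b: 0.26, c: -60.0, d: 0.0}
  v0: -62.0
  n_steps: 15100
  segments:
    - {start: [0.2, 0.0], end: [0.2, 5.0], amp: 2.0}
k:
  label: resonator
  # resonant pulse pair (gap ~ one subthreshold oscillation period, 40 ms)
  # fires; the second, off-resonance pair (gap 20 ms) does not
  params: {a: 0.1, b: 0.26, c: -60.0, d: -1.0}
  v0: -62.5
  n_steps: 2366
  segments:
    - {start: [0.1, 0.0], end: [0.1, 4.0], amp: 0.65}
    - {start: [0.1, 40.0], end: [0.1, 44.0], amp: 0.65}
    - {start: [0.7, 0.0], end: [0.7, 4.0], amp: 0.65}
    - {start: [0.7, 20.0], end: [0.7, 24.0], amp: 0.65}
l:
  label: integrator
  # a close pulse pair (3 ms apart) sums to threshold; the distant pair
  # (10 ms apart) and a lone pulse stay subthreshold
  params: {a: 0.02, b: 0.2, c: -55.0, d: 6.0}
  v0: -70.0
  n_steps: 5300
  segments:
    - {start: [0.2, 0.0], end: [0.2, 2.0], amp: 8.0}
    - {start: [0.2, 5.0], end: [0.2, 7.0], amp: 8.0}
    - {start: [0.7, 0.0], end: [0.7, 2.0], amp: 8.0}
    - {start: [0.7, 10.0], end: [0.7, 12.0], amp: 8.0}
m:
  label: rebound spike
  params: {a: 0.03, b: 0.25, c: -60.0, d: 4.0}
  v0: -64.0
  n_steps: 3500
  segments:
    - {start: [0.2, 0.0], end: [0.2, 10.0], amp: -15.0}
n:
  label: rebound burst
  params: {a: 0.03, b: 0.25, c: -52.0, d: 0.0}
  v0: -64.0
  n_steps: 25000
  segments:
    - {start: [0.2, 0.0], end: [0.2, 5.0], amp: -15.0}
o:
  label: threshold variability
  params: {a: 0.03, b: 0.25, c: -60.0, d: 4.0}
  v0: -64.0
  n_steps: 6200
  segments:
    - {start: [0.1, 0.0], end: [0.1, 5.0], amp: 1.0}
    - {start: [0.7, 0.0], end: [0.7, 5.0], amp: -6.0}
    - {start: [0.7, 10.0], end: [0.7, 15.0], amp: 1.0}
p:
  label: bistability
  params: {a: 0.1, b: 0.26, c: -60.0, d: 0.0}
  v0: -61.0
  n_steps: 20000
  baseline: 0.24
  segments:
    - {start: [0.125, 0.0], end: [0.125, 5.0], amp: 1.24}
    - {start: [0.72, 0.0], end: [0.72, 5.0], amp: 1.24}
q:
  label: depolarizing after-potential
  params: {a: 1.0, b: 0.2, c: -60.0, d: -16.0}
  v0: -70.0
  n_steps: 1646
  segments:
    - {start: [0.2, 0.0], end: [0.2, 2.0], amp: 20.0}
r:
  label: accommodation
  # slow ramp stays below the quasi-static rheobase (~4) because the recovery
  # variable tracks the depolarization; the brief pulse outruns it and fires
  params: {a: 0.02, b: 0.2, c: -65.0, d: 6.0}
  v0: -70.0
  n_steps: 9500
  segments:
    - {start: [0.0, 0.0], end: [0.5, 0.0], amp: [0.0, 3.5]}
    - {start: [0.75, 0.0], end: [0.75, 6.0], amp: 8.0}
s:
  label: inhibition-induced spiking
  params: {a: -0.02, b: -1.0, c: -60.0, d: 8.0}
  v0: -63.8
  n_steps: 20000
  baseline: 80.0
  segments:
    - {start: [0.15, 0.0], end: [0.8, 0.0], amp: 75.0}
t:
  label: inhibition-induced bursting
  # positive d keeps the unstable recovery variable bounded over long windows
  params: {a: -0.026, b: -1.0, c: -45.0, d: 2.0}
  v0: -63.8
  n_steps: 20000
  baseline: 80.0
  segments:
    - {start: [0.15, 0.0], end: [0.8, 0.0], amp: 75.0}
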