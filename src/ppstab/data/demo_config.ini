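# Demo pipeline: a helical toy receptor with a short extended partner that
# progressively dissociates.  Fully synthetic; completes in well under a
# minute.

[pipeline]
seed = 7
label = demo-dissociation

[receptor]
sequence = AEALKKALDEALKKALEALKKALG
conformation = helical

[partner]
sequence = AEKLAELKAL
conformation = extended

[complex]
gap = 4.0
axis = x

[trajectory]
kind = dissociating
n_frames = 100
sigma = 0.05
drift = 0.05

[analysis]
contact_cutoff = 5.0
contact_mode = calpha
n_poses = 5
salt_bridge_cutoff = 4.0
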