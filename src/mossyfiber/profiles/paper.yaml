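# Reserved slot for the mossy-fiber-bouton channel kinetics of the published
# model this package re-implements.  The rate equations and constants are not
# printed in the article text; they live in NMODL files in the ModelDB
# database:
#
#   accession 128079 : hhmfb.mod  (HH-type Na+/K+/leak set fitted to mossy
#                                  fiber boutons; its K+ is non-inactivating)
#                      KIn.mod    (HH model of inactivating K+ channels with
#                                  Kv1.4 kinetics)
#   accession 2018003: the complete afterdischarge model deposit
#
# To enable quantitative reproduction, transcribe each gate's alpha/beta (or
# x_inf/tau) parameterizations and exponents from those files into the
# 'channels' section below using the same schema as profiles/generic.yaml
# (channels: na, k_inactivating, k_noninactivating), then delete the
# 'status' line.  Constants are deliberately NOT guessed here.
name: paper
status: unpopulated
note: >
  Transcribe gate rate constants from ModelDB accession 128079 (hhmfb.mod,
  KIn.mod; deposit 2018003) into the 'channels' section of this file
  (src/mossyfiber/profiles/paper.yaml), following the schema of
  profiles/generic.yaml, then remove the 'status: unpopulated' line.
channels: {}
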