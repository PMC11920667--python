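# Patient interaction protocol.
# Reconstruction of the published patient protocol from the generic
# interaction model and the three scenario walkthroughs; the original
# full listing is available only as a figure.
#
# Guard predicates are resolved against the patient policy at run time:
# satisfied / rejects_outright / interested_in / opposes apply while a
# plan is under evaluation; persuaded / unpersuaded apply after a
# persuasion attempt and are driven by the personality model.

a(patient(), P) ::
    assert(disease, plan) <= a(doctor(), D)
    then
    a(patient_evaluating(), P)

a(patient_evaluating(), P) ::
    (
        accept(plan) => a(doctor(), D) <- satisfied(plan)
    or
        refuse(plan) => a(doctor(), D) <- rejects_outright(plan)
        then
        a(patient_awaiting_retraction(), P)
    or
        question(disease, plan) => a(doctor(), D) <- interested_in(disease, plan)
        then
        justify(disease, plan, support_arguments) <= a(doctor(), D)
        then
        a(patient_evaluating(), P)
    or
        rebuttal(intervention, against_arguments) => a(doctor(), D) <- opposes(intervention)
        then
        persuade(intervention, support_arguments) <= a(doctor(), D)
        then
        a(patient_deciding(), P)
    )

a(patient_deciding(), P) ::
    (
        accept(plan) => a(doctor(), D) <- persuaded(intervention)
    or
        refuse(plan) => a(doctor(), D) <- unpersuaded(intervention)
        then
        a(patient_awaiting_retraction(), P)
    or
        question(disease, plan) => a(doctor(), D) <- interested_in(disease, plan)
        then
        justify(disease, plan, support_arguments) <= a(doctor(), D)
        then
        a(patient_evaluating(), P)
    )

a(patient_awaiting_retraction(), P) ::
    retract(plan) <= a(doctor(), D)
    then
    a(patient(), P)
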