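# Physician interaction protocol.
# Reconstruction of the published physician protocol from the generic
# interaction model and the three scenario walkthroughs; the original
# full listing is available only as a figure.
#
# Clauses: the doctor opens with an assertion of the recommended plan,
# then loops through response handling (doctor_responding), persuasion
# outcomes (doctor_deciding) and retraction with plan substitution
# (doctor_retracting).  A bare a(role(), D) term is a role call: the
# protocol continues as that clause.

a(doctor(guideline), D) ::
    assert(disease, plan) => a(patient(), P)
    then
    a(doctor_responding(), D)

a(doctor_responding(), D) ::
    (
        accept(plan) <= a(patient(), P)
    or
        refuse(plan) <= a(patient(), P)
        then
        a(doctor_retracting(), D)
    or
        question(disease, plan) <= a(patient(), P)
        then
        justify(disease, plan, support_arguments) => a(patient(), P) <- has_support(plan)
        then
        a(doctor_responding(), D)
    or
        rebuttal(intervention, against_arguments) <= a(patient(), P)
        then
        persuade(intervention, support_arguments) => a(patient(), P) <- has_support(intervention)
        then
        a(doctor_deciding(), D)
    )

a(doctor_deciding(), D) ::
    (
        accept(plan) <= a(patient(), P)
    or
        refuse(plan) <= a(patient(), P)
        then
        a(doctor_retracting(), D)
    or
        question(disease, plan) <= a(patient(), P)
        then
        justify(disease, plan, support_arguments) => a(patient(), P) <- has_support(plan)
        then
        a(doctor_responding(), D)
    )

a(doctor_retracting(), D) ::
    retract(plan) => a(patient(), P)
    then
    a(doctor(), D) <- has_alternative(plan)
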