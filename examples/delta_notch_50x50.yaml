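assignment: {default: delta_notch}
grid: {height: 50, width: 50, wrap: none}
initial_state:
  components: {Green: 0, Red: 0}
  default: 0
inputs:
  integration:
    Green:
    - {level: 1, rule: 'Red>=1 [1:1] atleast 1'}
models:
  delta_notch: {sbml: "<?xml version='1.0' encoding='UTF-8'?>\n<sbml xmlns=\"http://www.sbml.org/sbml/level3/version1/core\"\
      \ xmlns:qual=\"http://www.sbml.org/sbml/level3/version1/qual/version1\" level=\"3\" version=\"1\"\
      \ qual:required=\"true\">\n  <model id=\"delta_notch\">\n    <listOfCompartments>\n      <compartment\
      \ id=\"default\" constant=\"true\"/>\n    </listOfCompartments>\n    <qual:listOfQualitativeSpecies>\n\
      \      <qual:qualitativeSpecies qual:id=\"Green\" qual:compartment=\"default\" qual:constant=\"\
      true\" qual:maxLevel=\"1\"/>\n      <qual:qualitativeSpecies qual:id=\"Red\" qual:compartment=\"\
      default\" qual:constant=\"false\" qual:maxLevel=\"1\"/>\n    </qual:listOfQualitativeSpecies>\n\
      \    <qual:listOfTransitions>\n      <qual:transition qual:id=\"tr_Red\">\n        <qual:listOfInputs>\n\
      \          <qual:input qual:id=\"tr_Red_in_0\" qual:qualitativeSpecies=\"Green\" qual:transitionEffect=\"\
      none\"/>\n        </qual:listOfInputs>\n        <qual:listOfOutputs>\n          <qual:output qual:id=\"\
      tr_Red_out\" qual:qualitativeSpecies=\"Red\" qual:transitionEffect=\"assignmentLevel\"/>\n     \
      \   </qual:listOfOutputs>\n        <qual:listOfFunctionTerms>\n          <qual:functionTerm qual:resultLevel=\"\
      1\">\n            <ns0:math xmlns:ns0=\"http://www.w3.org/1998/Math/MathML\">\n              <ns0:apply>\n\
      \                <ns0:not/>\n                <ns0:apply>\n                  <ns0:geq/>\n       \
      \           <ns0:ci> Green </ns0:ci>\n                  <ns0:cn type=\"integer\"> 1 </ns0:cn>\n\
      \                </ns0:apply>\n              </ns0:apply>\n            </ns0:math>\n          </qual:functionTerm>\n\
      \          <qual:defaultTerm qual:resultLevel=\"0\"/>\n        </qual:listOfFunctionTerms>\n   \
      \   </qual:transition>\n    </qual:listOfTransitions>\n  </model>\n</sbml>\n"}
simulation: {alpha: 0.25, bernoulli: false, max_steps: 1000, scheme: alpha_async, seed: 1}
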