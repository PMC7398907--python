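<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2" level="3" version="1" fbc:required="false">
  <model id="RAND0" name="random balanced model (seed 0)" fbc:strict="false">
    <listOfCompartments>
      <compartment id="c" constant="true"/>
      <compartment id="e" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="s0_e" name="substrate" compartment="e" initialAmount="0" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false" fbc:charge="0" fbc:chemicalFormula="E6"/>
      <species id="s0_c" name="species 0" compartment="c" initialAmount="0" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false" fbc:charge="0" fbc:chemicalFormula="E6"/>
      <species id="s1_c" name="species 1" compartment="c" initialAmount="0" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false" fbc:charge="0" fbc:chemicalFormula="E4"/>
      <species id="s2_c" name="species 2" compartment="c" initialAmount="0" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false" fbc:charge="0" fbc:chemicalFormula="E4"/>
      <species id="s3_c" name="species 3" compartment="c" initialAmount="0" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false" fbc:charge="0" fbc:chemicalFormula="E2"/>
      <species id="s4_c" name="species 4" compartment="c" initialAmount="0" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false" fbc:charge="0" fbc:chemicalFormula="E2"/>
      <species id="s5_c" name="species 5" compartment="c" initialAmount="0" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false" fbc:charge="0" fbc:chemicalFormula="E1"/>
      <species id="biomass_c" name="biomass" compartment="c" initialAmount="0" hasOnlySubstanceUnits="false" boundaryCondition="true" constant="false"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="EX_s0_lb" value="-1000" constant="true"/>
      <parameter id="EX_s0_ub" value="1000" constant="true"/>
      <parameter id="T_s0_lb" value="0" constant="true"/>
      <parameter id="T_s0_ub" value="1000" constant="true"/>
      <parameter id="R0_lb" value="-1000" constant="true"/>
      <parameter id="R0_ub" value="1000" constant="true"/>
      <parameter id="R1_lb" value="0" constant="true"/>
      <parameter id="R1_ub" value="1000" constant="true"/>
      <parameter id="R2_lb" value="0" constant="true"/>
      <parameter id="R2_ub" value="1000" constant="true"/>
      <parameter id="R3_lb" value="0" constant="true"/>
      <parameter id="R3_ub" value="1000" constant="true"/>
      <parameter id="R4_lb" value="0" constant="true"/>
      <parameter id="R4_ub" value="1000" constant="true"/>
      <parameter id="BIOMASS_lb" value="0" constant="true"/>
      <parameter id="BIOMASS_ub" value="1000" constant="true"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="EX_s0" reversible="true" fast="false" fbc:lowerFluxBound="EX_s0_lb" fbc:upperFluxBound="EX_s0_ub">
        <listOfReactants>
          <speciesReference species="s0_e" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
      <reaction id="T_s0" reversible="false" fast="false" fbc:lowerFluxBound="T_s0_lb" fbc:upperFluxBound="T_s0_ub">
        <listOfReactants>
          <speciesReference species="s0_e" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="s0_c" stoichiometry="1" constant="true"/>
        </listOfProducts>
      </reaction>
      <reaction id="R0" reversible="true" fast="false" fbc:lowerFluxBound="R0_lb" fbc:upperFluxBound="R0_ub">
        <listOfReactants>
          <speciesReference species="s0_c" stoichiometry="2" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="s1_c" stoichiometry="3" constant="true"/>
        </listOfProducts>
      </reaction>
      <reaction id="R1" reversible="false" fast="false" fbc:lowerFluxBound="R1_lb" fbc:upperFluxBound="R1_ub">
        <listOfReactants>
          <speciesReference species="s1_c" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="s2_c" stoichiometry="1" constant="true"/>
        </listOfProducts>
      </reaction>
      <reaction id="R2" reversible="false" fast="false" fbc:lowerFluxBound="R2_lb" fbc:upperFluxBound="R2_ub">
        <listOfReactants>
          <speciesReference species="s2_c" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="s3_c" stoichiometry="2" constant="true"/>
        </listOfProducts>
      </reaction>
      <reaction id="R3" reversible="false" fast="false" fbc:lowerFluxBound="R3_lb" fbc:upperFluxBound="R3_ub">
        <listOfReactants>
          <speciesReference species="s3_c" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="s4_c" stoichiometry="1" constant="true"/>
        </listOfProducts>
      </reaction>
      <reaction id="R4" reversible="false" fast="false" fbc:lowerFluxBound="R4_lb" fbc:upperFluxBound="R4_ub">
        <listOfReactants>
          <speciesReference species="s4_c" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="s5_c" stoichiometry="2" constant="true"/>
        </listOfProducts>
      </reaction>
      <reaction id="BIOMASS" reversible="false" fast="false" fbc:lowerFluxBound="BIOMASS_lb" fbc:upperFluxBound="BIOMASS_ub">
        <listOfReactants>
          <speciesReference species="s5_c" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="biomass_c" stoichiometry="1" constant="true"/>
        </listOfProducts>
      </reaction>
    </listOfReactions>
    <fbc:listOfObjectives fbc:activeObjective="obj">
      <fbc:objective fbc:id="obj" fbc:type="maximize">
        <fbc:listOfFluxObjectives>
          <fbc:fluxObjective fbc:reaction="BIOMASS" fbc:coefficient="1"/>
        </fbc:listOfFluxObjectives>
      </fbc:objective>
    </fbc:listOfObjectives>
  </model>
</sbml>
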