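<?xml version='1.0' encoding='utf-8'?>
<garm_results>
  <meta pattern="_ AND (_ OR _) -&gt; _" input="golden_table.csv" n_rows="100" n_columns="6">
    <thresholds min_support="12" min_confidence="0.7500" min_lift="1.6000" min_leverage="-0.2500" max_value_set_size="2" simplify_tolerance="0.0200" />
  </meta>
  <rules>
    <rule text="x=a AND (y=b OR z=c) -&gt; w=d">
      <lhs>
        <clause>
          <eq column="x" values="a" />
        </clause>
        <clause>
          <eq column="y" values="b" />
          <eq column="z" values="c" />
        </clause>
      </lhs>
      <rhs>
        <eq column="w" values="d" />
      </rhs>
      <metrics support="36" lhs_support="40" rhs_support="39" confidence="0.9000" lift="2.3077" leverage="0.2040" />
    </rule>
    <rule text="x=a AND y=b -&gt; w=d">
      <lhs>
        <clause>
          <eq column="x" values="a" />
        </clause>
        <clause>
          <eq column="y" values="b" />
        </clause>
      </lhs>
      <rhs>
        <eq column="w" values="d" />
      </rhs>
      <metrics support="21" lhs_support="25" rhs_support="39" confidence="0.8400" lift="2.1538" leverage="0.1125" />
    </rule>
    <rule text="x=a AND z=c -&gt; w=d">
      <lhs>
        <clause>
          <eq column="x" values="a" />
        </clause>
        <clause>
          <eq column="z" values="c" />
        </clause>
      </lhs>
      <rhs>
        <eq column="w" values="d" />
      </rhs>
      <metrics support="21" lhs_support="25" rhs_support="39" confidence="0.8400" lift="2.1538" leverage="0.1125" />
    </rule>
    <rule text="x=ao AND z=c -&gt; w=d">
      <lhs>
        <clause>
          <eq column="x" values="ao" />
        </clause>
        <clause>
          <eq column="z" values="c" />
        </clause>
      </lhs>
      <rhs>
        <eq column="w" values="d" />
      </rhs>
      <metrics support="21" lhs_support="27" rhs_support="39" confidence="0.7778" lift="1.9943" leverage="0.1047" />
    </rule>
    <rule text="x=a AND y=bo -&gt; w=d">
      <lhs>
        <clause>
          <eq column="x" values="a" />
        </clause>
        <clause>
          <eq column="y" values="bo" />
        </clause>
      </lhs>
      <rhs>
        <eq column="w" values="d" />
      </rhs>
      <metrics support="36" lhs_support="48" rhs_support="39" confidence="0.7500" lift="1.9231" leverage="0.1728" />
    </rule>
    <rule text="y=b AND z=n -&gt; w=d">
      <lhs>
        <clause>
          <eq column="y" values="b" />
        </clause>
        <clause>
          <eq column="z" values="n" />
        </clause>
      </lhs>
      <rhs>
        <eq column="w" values="d" />
      </rhs>
      <metrics support="15" lhs_support="20" rhs_support="39" confidence="0.7500" lift="1.9231" leverage="0.0720" />
    </rule>
    <rule text="x=an AND x=no -&gt; w=n">
      <lhs>
        <clause>
          <eq column="x" values="an" />
        </clause>
        <clause>
          <eq column="x" values="no" />
        </clause>
      </lhs>
      <rhs>
        <eq column="w" values="n" />
      </rhs>
      <metrics support="20" lhs_support="20" rhs_support="61" confidence="1.0000" lift="1.6393" leverage="0.0780" />
    </rule>
    <rule text="x=n -&gt; w=n">
      <lhs>
        <clause>
          <eq column="x" values="n" />
        </clause>
      </lhs>
      <rhs>
        <eq column="w" values="n" />
      </rhs>
      <metrics support="20" lhs_support="20" rhs_support="61" confidence="1.0000" lift="1.6393" leverage="0.0780" />
    </rule>
    <rule text="y=bn AND y=no -&gt; w=n">
      <lhs>
        <clause>
          <eq column="y" values="bn" />
        </clause>
        <clause>
          <eq column="y" values="no" />
        </clause>
      </lhs>
      <rhs>
        <eq column="w" values="n" />
      </rhs>
      <metrics support="19" lhs_support="19" rhs_support="61" confidence="1.0000" lift="1.6393" leverage="0.0741" />
    </rule>
    <rule text="y=n -&gt; w=n">
      <lhs>
        <clause>
          <eq column="y" values="n" />
        </clause>
      </lhs>
      <rhs>
        <eq column="w" values="n" />
      </rhs>
      <metrics support="19" lhs_support="19" rhs_support="61" confidence="1.0000" lift="1.6393" leverage="0.0741" />
    </rule>
    <rule text="x=no AND (y=n OR z=c) -&gt; w=n">
      <lhs>
        <clause>
          <eq column="x" values="no" />
        </clause>
        <clause>
          <eq column="y" values="n" />
          <eq column="z" values="c" />
        </clause>
      </lhs>
      <rhs>
        <eq column="w" values="n" />
      </rhs>
      <metrics support="16" lhs_support="16" rhs_support="61" confidence="1.0000" lift="1.6393" leverage="0.0624" />
    </rule>
    <rule text="x=a AND (y=n OR z=o) -&gt; w=n">
      <lhs>
        <clause>
          <eq column="x" values="a" />
        </clause>
        <clause>
          <eq column="y" values="n" />
          <eq column="z" values="o" />
        </clause>
      </lhs>
      <rhs>
        <eq column="w" values="n" />
      </rhs>
      <metrics support="14" lhs_support="14" rhs_support="61" confidence="1.0000" lift="1.6393" leverage="0.0546" />
    </rule>
    <rule text="x=an AND z=o -&gt; w=n">
      <lhs>
        <clause>
          <eq column="x" values="an" />
        </clause>
        <clause>
          <eq column="z" values="o" />
        </clause>
      </lhs>
      <rhs>
        <eq column="w" values="n" />
      </rhs>
      <metrics support="12" lhs_support="12" rhs_support="61" confidence="1.0000" lift="1.6393" leverage="0.0468" />
    </rule>
  </rules>
</garm_results>
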